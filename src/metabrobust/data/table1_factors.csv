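# Factor specifications for the packaged 15-run robustness worksheet.
# Levels are transcribed as printed. Note: the vortex1 column is labelled
# [min] in the source worksheet but its levels (165/180/195) are consistent
# with the protocol's "3 min of vortexing" only if the unit is actually
# seconds; the printed label and numbers are preserved unchanged here.
name,units,low,centre,high,is_dummy
Metanol,µL,98,100,102,false
Mtbe1,µL,196,200,204,false
vortex1,min,165,180,195,false
MTBE2,µL,315,320,325,false
H20,µL,226,230,234,false
Vortex2,min,50,60,70,false
Centrifugation,min,9,10,11,false
Volume for Evaporation,µL,196,200,204,false
Evaporation Temperature,°C,33,35,37,false
Solvent Volume for Reconstitution,µL,196,200,204,false
Dummy Factor,,-1,0,1,true
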