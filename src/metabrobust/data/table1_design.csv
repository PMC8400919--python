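# Packaged 15-run Plackett-Burman robustness worksheet (physical values).
# 12 factorial runs for 10 protocol factors plus one dummy factor, with
# 3 centre-point runs interleaved at ordinal positions 6, 10 and 15.
run,pattern,Metanol,Mtbe1,vortex1,MTBE2,H20,Vortex2,Centrifugation,Volume for Evaporation,Evaporation Temperature,Solvent Volume for Reconstitution,Dummy Factor
1,+---+--+-++,102,196,165,315,234,50,9,204,33,204,1
2,+++---+--+-,102,204,195,315,226,50,11,196,33,204,-1
3,--+-+++---+,98,196,195,315,234,70,11,196,33,196,1
4,-+--+-+++--,98,204,165,315,234,50,11,204,37,196,-1
5,---+--+-+++,98,196,165,325,226,50,11,196,37,204,1
6,0,100,200,180,320,230,60,10,200,35,200,0
7,+-+++---+--,102,196,195,325,234,50,9,196,37,196,-1
8,-+++---+--+,98,204,195,325,226,50,9,204,33,196,1
9,--+--+-+++-,98,196,195,315,226,70,9,204,37,204,-1
10,0,100,200,180,320,230,60,10,200,35,200,0
11,++---+--+-+,102,204,165,315,226,70,9,196,37,196,1
12,+++++++++++,102,204,195,325,234,70,11,204,37,204,1
13,+--+-+++---,102,196,165,325,226,70,11,204,33,196,-1
14,-+-+++---+-,98,204,165,325,234,70,9,196,33,204,-1
15,0,100,200,180,320,230,60,10,200,35,200,0
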