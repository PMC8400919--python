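"""Build the screening design used for robustness testing and decode it.

Generates a Plackett-Burman matrix for 10 protocol factors plus one dummy
(12 factorial runs), interleaves 3 centre points, validates the defining
balance/orthogonality properties and decodes a run of the packaged
worksheet into pipettable volumes.
"""

from metabrobust import (
    add_centre_points,
    decode_run,
    generate_pb_matrix,
    load_table1_design,
    validate_design,
)

# 11 coded factors -> smallest multiple of 4 above 11 is 12 runs
design = add_centre_points(generate_pb_matrix(11), 3)
print(f"runs: {len(design.runs)} ({design.n_factorial} factorial + {design.n_centre} centre)")
report = validate_design(design)
print(f"balanced and orthogonal: {report.ok}")

# the packaged physical worksheet: decode the all-high run (row 12)
table1 = load_table1_design()
physical = decode_run(table1.run("12"), table1.factors)
for factor in table1.factors[:4]:
    print(f"  {factor.name}: {physical[factor.name]} {factor.units}")
print("A '+' level sets each factor to its high value, e.g. 102 µL methanol;")
print("centre runs (pattern '0') sit at every factor's midpoint.")
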