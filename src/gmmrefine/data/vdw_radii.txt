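# Van der Waals radii (Angstrom) used for steric-clash detection.
# Element-level contact radii in the MolProbity / PDB-validation style.
# Format: element radius
H 1.17
C 1.70
N 1.55
O 1.40
P 1.80
S 1.80
SE 1.90
F 1.30
CL 1.77
BR 1.85
I 1.98
MG 1.57
ZN 1.39
FE 1.30
CA 1.71
NA 1.36
K 1.76
MN 1.30
CU 1.40
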