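# Ideal inter-residue link geometry (Engh-Huber-style restraints).
# kind bond|angle atoms... mean std
# "peptide" links residue i (C, CA, O) to residue i+1 (N, CA).
# "rna" links residue i (C3', O3') to residue i+1 (P, O5', OP1, OP2).
peptide bond C N 1.336 0.014
peptide angle CA C N 116.2 2.0
peptide angle O C N 123.2 1.6
peptide angle C N CA 121.7 2.5
rna bond O3' P 1.607 0.015
rna angle C3' O3' P 119.7 1.5
rna angle O3' P O5' 104.0 1.9
rna angle O3' P OP1 108.1 2.9
rna angle O3' P OP2 108.3 2.9
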