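# Default restraint standard deviations for intra-residue terms whose means
# are taken from the chemical-component ideal coordinates.
# key value
bond_std 0.021
angle_std 2.0
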