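name	mass_shift	charge	mode
M+H	1.007276	1	positive
M+Na	22.989221	1	positive
M+H-H2O	-17.003288	1	positive
M-H	-1.007276	1	negative
M+Cl	34.969401	1	negative
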