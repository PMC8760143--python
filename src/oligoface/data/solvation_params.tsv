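# atomic solvation parameters sigma (kcal/mol/Angstrom^2) by element class
# carbon burial is favourable (hydrophobic), polar burial unfavourable
C	0.0118
N	-0.0183
O	-0.0175
S	0.0118
P	-0.0183
DEFAULT	0.0
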