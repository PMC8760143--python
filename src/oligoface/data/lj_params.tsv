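# united-atom Lennard-Jones classes by element: epsilon (kcal/mol), sigma (Angstrom)
# coarse OPLS-flavoured values; DEFAULT is the fallback class
C	0.105	3.75
N	0.170	3.25
O	0.210	2.96
S	0.250	3.55
P	0.200	3.74
MG	0.875	1.87
FE	0.013	2.59
H	0.030	2.42
DEFAULT	0.105	3.75
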