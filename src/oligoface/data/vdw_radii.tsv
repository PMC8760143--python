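# element -> van der Waals radius (Angstrom); DEFAULT is the fallback
C	1.70
N	1.55
O	1.52
S	1.80
MG	1.73
P	1.80
H	1.20
FE	1.40
DEFAULT	1.70
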