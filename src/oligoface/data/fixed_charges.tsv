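# residue-independent backbone partial charges (e) for non-titratable atoms;
# side-chain atoms outside ionizable groups carry zero. Dipolar, net-neutral
# per residue (no hydrogens in cryo-EM models).
N	-0.35
CA	0.35
C	0.45
O	-0.45
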