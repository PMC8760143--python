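# residue name -> cofactor kind (editable; carotenoids/lipids may be absent
# from a deposition and can be added or removed here without code changes)
CLA	chlorophyll_a
BCR	beta_carotene
PQN	phylloquinone
SF4	FeS_cluster
FES	FeS_cluster
LHG	lipid
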