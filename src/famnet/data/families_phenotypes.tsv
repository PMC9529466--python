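family_id	individual_id	phenotype	score
1	FA1	BAP
1	MO1	NT
1	AU53	ASD
1	AU54	ASD
1	SIB1	NT
2	FA2	BAP
2	MO2	BAP
2	AU209	ASD
2	AU210	ASD
2	SIB2	NT
3	FA3	BAP
3	MO3	NT
3	AU301	ASD
3	AU302	ASD
4	FA4A	NT
4	FA4B	NT
4	MO4	BAP
4	AU216	ASD
4	AU217	ASD
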