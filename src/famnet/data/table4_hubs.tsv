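family	entrez_id	gene	degree
1	9759	HDAC4	202
1	6925	TCF4	54
1	5521	PPP2R2B	51
1	7276	TTR	50
2	9759	HDAC4	202
2	7273	TTN	104
2	51592	TRIM33	73
2	7249	TSC2	62
2	6925	TCF4	54
2	5521	PPP2R2B	51
3	9759	HDAC4	202
3	7273	TTN	104
3	51592	TRIM33	73
3	6925	TCF4	54
3	5521	PPP2R2B	51
4	1080	CFTR	222
4	9759	HDAC4	202
4	51592	TRIM33	73
4	4204	MECP2	60
4	6925	TCF4	54
4	5521	PPP2R2B	51
4	64127	NOD2	50
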