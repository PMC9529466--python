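no	gene	hgvs	sift	polyphen	clinical_significance	dbsnp_id	maf	consequence	families
1	BCHE	NM_000055.2:c.293A>G	deleterious	possibly_damaging	likely_pathogenic	rs1799807	0.00599	missense	1
2	RETREG1	NM_019000.4:c.503C>G			pathogenic	rs137852739	0.00020	stop_gained	1;2;3;4
3	NPHS1	NM_004646.3:c.2869G>A	deleterious	probably_damaging	likely_pathogenic	rs114849139	0.00280	missense	2
4	CLN6	NM_017882.3:c.307C>T	deleterious	probably_damaging	conflicting	rs201095412	0.00020	missense	4
5	MYBPC3	NM_000256.3:c.649A>G	deleterious	possibly_damaging	conflicting	rs138753870	0.00180	missense	4
6	TSHR	NM_000369.5:c.1349G>A	deleterious	probably_damaging	conflicting	rs189261858	0.00020	missense	4
7	SPINK1	NM_003122.4:c.194+2T>C			conflicting	rs148954387	0.00080	splice_donor	3
8	AMPD1	NM_000036.3:c.860A>T	deleterious	probably_damaging	conflicting	rs34526199	0.01098	missense	1;4
9	PLEKHG5	NM_020631.5:c.2485G>T	deleterious	possibly_damaging	conflicting	rs200162521	0.00020	missense	1
10	RYR1	NM_000540.3:c.9713A>G	deleterious	possibly_damaging	conflicting	rs200950673	0.00020	missense	4
11	COL6A2	NM_001849.4:c.2795C>T	tolerated	benign	conflicting	rs117725825	0.00160	missense	4
12	SCN5A	NM_000335.5:c.4821C>T			conflicting	rs45437099	0.00100	synonymous	3;4
13	TTN	NM_001267550.2:c.102595A>G		benign	conflicting	rs56347248	0.00599	missense	3
14	TTN	NM_001267550.2:c.101891G>A		benign	conflicting	rs55669553	0.00599	missense	3
15	TTN	NM_001267550.2:c.95297C>T		probably_damaging	conflicting	rs191484894	0.00599	missense	3
16	TTN	NM_001267550.2:c.90536G>A		probably_damaging	conflicting	rs149567378	0.00619	missense	3
17	TTN	NM_001267550.2:c.82560C>A		probably_damaging	conflicting	rs56264840	0.00579	missense	3
18	TTN	NM_001267550.2:c.49919G>C		probably_damaging	conflicting	rs55663050	0.00599	missense	3
19	TTN	NM_001267550.2:c.47545C>A		benign	conflicting	rs146181477	0.00599	missense	3
20	TTN	NM_001267550.2:c.1137A>G			conflicting	rs55972547	0.00599	synonymous	3
21	CACNA2D4	NM_172364.5:c.2120G>A	tolerated	possibly_damaging	conflicting	rs76064926	0.00719	missense	3
22	EFHC1	NM_018100.4:c.685T>C	tolerated	benign	conflicting	rs137852776	0.00180	missense	3
23	SPTA1	NM_003126.4:c.6421C>T	deleterious	probably_damaging	conflicting	rs41273519	0.00160	missense	4
24	NEB	NM_001271208.2:c.571G>C	deleterious	probably_damaging	conflicting	rs35686968	0.00719	missense	3
25	CYP27A1	NM_000784.4:c.1151C>T	deleterious	probably_damaging	conflicting	rs41272687	0.00859	missense	3
26	LPL	NM_000237.3:c.953A>G	tolerated	benign	conflicting	rs268	0.00519	missense	1
27	MEFV	NM_000243.2:c.1772T>C	tolerated	benign	conflicting	rs11466045	0.00439	missense	1
28	NOD2	NM_001370466.1:c.332G>A	deleterious	benign	conflicting	rs104895456	0.00020	missense	4
29	VSX1	NM_014588.5:c.479G>A	tolerated	benign	conflicting	rs74315433	0.00260	missense	4
30	DOCK6	NM_020812.4:c.4862T>C	deleterious	benign	conflicting	rs201738818	0.00120	missense	2
31	FANCC	NM_000136.3:c.77C>T	deleterious	probably_damaging	conflicting	rs1800361	0.00260	missense	2
32	NPC2	NM_006432.4:c.441+1G>A			conflicting	rs140130028	0.00100	splice_donor	3;4
33	CFTR	NM_000492.4:c.1584G>A			conflicting	rs1800095	0.01058	synonymous	4
34	TTN	NM_001267550.2:c.14698G>A		probably_damaging	conflicting	rs72648923	0.00180	missense	2
35	FKTN	NM_001079802.2:c.1297A>G	tolerated	benign	conflicting	rs141918432	0.00100	missense	4
36	IFIH1	NM_022168.4:c.1879G>T			conflicting	rs35744605	0.00140	stop_gained	1
37	TTN	NM_001267550.2:c.48727C>T		benign	conflicting	rs72677242	0.00160	missense	2
38	TSC2	NM_000548.5:c.1939G>A	deleterious	probably_damaging	conflicting	rs45509392	0.00040	missense	2
39	TTR	NM_000371.4:c.417G>A			conflicting	rs2276382	0.00359	synonymous	1
40	TTN	NM_001267550.2:c.65775C>T			conflicting	rs72646867	0.00160	synonymous	2
41	LDLR	NM_000527.5:c.148G>T	tolerated	benign	conflicting	rs137853960	0.00060	missense	1
42	DNAAF11	NM_012472.6:c.1391C>T	deleterious	probably_damaging	conflicting	rs139131485	0.00080	missense	1
43	SOX3	NM_005634.2:c.157G>C	tolerated	benign	conflicting	rs200361128	0.00265	missense	4
44	C6	NM_000065.4:c.2381+2T>C			conflicting	rs76202909	0.00120	splice_donor	1
45	SCN1B	NM_001037.5:c.28G>A	tolerated	possibly_damaging	conflicting	rs72552027	0.00319	missense	2
46	PHYH	NM_006214.4:c.734G>A	deleterious	benign	conflicting	rs62619919	0.00539	missense	4
47	CACNB2	NM_201596.3:c.1816C>T	deleterious	probably_damaging	conflicting	rs61733968	0.00439	missense	4
48	OCA2	NM_000275.3:c.1441G>A	tolerated	possibly_damaging	conflicting	rs74653330	0.00799	missense	1;3
49	WNT10A	NM_025216.3:c.511C>T	deleterious	probably_damaging	conflicting	rs116998555	0.00319	missense	1;2;3;4
50	MECP2	NM_001110792.2:c.638C>T	tolerated	benign	likely_benign	rs61748381	0.00477	missense	4
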