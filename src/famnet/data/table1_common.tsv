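no	dbsnp_id	region	mapped_genes	consequence	freqs	families
1	rs6537825		TRIM33	missense	0.085217;0.092924;0.115222	2;3;4
2	rs926938		AMPD1	intergenic	0.474113;0.499930;0.480234	1;2;3;4
3	rs6538761	12q23.1	Y_RNA	intron	0.349973;0.339321;0.332810	1;2;3;4
4	rs4307059			intron	0.354951	1;2;3;4
5	rs12543592	8q24.13	SMILR	intron	0.450958	1;2;3;4
6	rs2447097	17p13.3	SGSM2	intron	0.421255;0.457423;0.422399	1;2;3;4
7	rs11184553	1p21.1	CDK4P1	intergenic	0.487925;0.43423	2;3;4
8	rs325485	5q21.2	LOC105379109	intron	0.336235;0.383385;0.343482	1
9	rs17693963	6p22.1	GPR89P,RSL24D1P1	intergenic	0.07605	4
10	rs1021363	10q25.1	SORCS3	intron	0.253202;0.261206;0.30279	1;2;3;4
11	rs10149470	14q32.33	RNU7-160P,BAG5	regulatory_region	0.453024;0.450706;0.47706	1;2;3;4
12	rs1620977	1p31.1	NEGR1	intron	0.201863;0.267664;0.204083	1;3;4
13	rs1452075	3p14.2	CADPS	intron	0.275542;0.263913;0.264183	1;2;3
14	rs34509057	5q33.2	GALNT10	intron	0.165276;0.178673;0.20461	1
15	rs55661361	11q24.2	NRGN	intron	0.434229;0.436872;0.29541	1;2;3;4
16	rs11682175	2p16.1	ACTG1P22	intron	0.378579;0.381349;0.44219	1;2;3
17	rs1378559	Xp22.12	LOC105373146	intron	0.102214;0.103850;0.13327	2;4
18	rs2522831	7q21.11	PCLO	intron	0.420114;0.451828;0.412847	1;2;3;4
19	rs10164055	18q21.2	DCC	intron	0.292176;0.316869	1
20	rs12967143	18q21.2	TCF4	intron	0.475005;0.453865	1;2;3;4
21	rs12624433	20q13.12	SLC12A5	intron	0.196184;0.202170;0.18751	1;2;4
22	rs11874716	18q21.2	LINC01929	intergenic	0.397461;0.33788	2;4
23	rs10791097		LINC02551	intron	0.396830;0.404173;0.42591	1;2;3;4
24	rs1353545	3p14.2	FHIT	intron	0.377823;0.359634;0.35375	1;2;3
25	rs75968099	3p22.2	HSPD1P6,LINC02033	intergenic	0.250519;0.259647;0.31905	1;3
26	rs77502336	11q24.1	GRAMD1B	intron	0.271272;0.270710;0.28936	2;3;4
27	rs3849046	5q31.2	ETF1	intron	0.492134;0.49090	1;2;3;4
28	rs2332700	14q24.2	RGS6	intron	0.237391;0.240436;0.25146	1;2;3;4
29	rs1024582	12p13.33	CACNA1C	intron	0.235419;0.300859	1;2;4
30	rs10520163	4q33	CLCN3	intron	0.499018;0.442945;0.440639	1;2;3;4
31	rs3735025	7q33	DGKI	three_prime_UTR	0.288232;0.286664;0.33618	1;2;3;4
32	rs171748	5q12.1	SMIM15-AS1	intron	0.389289;0.395943	1;2;3;4
33	rs4523957	17p13.3	SRR	intron	0.460962;0.456330;0.40695	3;4
34	rs1977199	6p22.2	BTN2A1	intron	0.335797;0.332093	1;2;3;4
35	rs4129585		TSNARE1	intron	0.312399;0.415568;0.327265	1;2;3;4
36	rs12887734	14q32.33	COA8	intron	0.248290;0.258449;0.27298	1;2;3;4
37	rs12522290	5q33.2	GRIA1	regulatory_region	0.115290;0.121303;0.14219	4
38	rs73416724	6p21.1	ZNF318	noncoding_transcript_exon	0.108221;0.106380;0.11175	1
39	rs7893279		CACNB2	intron	0.102354;0.102536;0.11104	1;3;4
40	rs707939	6p21.33	MSH5,MSH5-SAPCD1	intron	0.359700;0.258582;0.343005	1;2;3;4
41	rs67756423	8q24.3	TSNARE1	intron	0.215191;0.207610	2;4
42	rs5995756		CACNA1I	intron	0.401938;0.443669;0.383588	1;2;3;4
43	rs911186	6p22.1	MIR3143,RPL10P2	intergenic	0.254724;0.224222;0.247801	3;4
44	rs8042374	15q25.1	CHRNA3	intron	0.316495;0.250356;0.286205	1;2;3;4
45	rs17194490	3p26.3	CNTN4	intron	0.14142	3;4
46	rs13218591	6p22.2	BTN3A2	three_prime_UTR	0.302939;0.299397;0.30182	3;4
47	rs3132581	6p21.33	MUCL3,SFTA2	intron	0.089059;0.124702;0.094994	4
48	rs2675968	2q37.1	SNORC	intron	0.301515;0.301837;0.30176	1;2
49	rs703970	10q22.3	ZMIZ1	intron	0.380653;0.408319;0.379565	2;3;4
50	rs7597593	2q32.1	ZNF804A	intron	0.475753;0.403458;0.470696	3;4
51	rs10250997	7q33	ZP3P2	intergenic	0.144509;0.114385;0.147202	2;4
52	rs9834970	3p22.2	HSPD1P6,LINC02033	regulatory_region	0.455287;0.498254;0.443239	1;2;3
53	rs7565792	2p16.3	FOXN2,PPP1R21-DT	intergenic	0.433488;0.403518	1;2;4
54	rs6602217	10p14	LOC105376387	intron	0.084034;0.158298;0.156390	3;4
55	rs12325410	16p13.2	LOC101927026	intron	0.156282;0.172092;0.163921	1;2;4
56	rs8058295	16p13.2	GRIN2A	intron	0.320919;0.325310;0.28528	3;4
57	rs6694545			other	0.268749;0.433889;0.417634	1;3;4
58	rs2609653	8p12	RPL10AP3	intergenic	0.054090;0.051313;0.059383	2;4
59	rs9951150	18q21.2	RNA5SP459,TCF4	intergenic	0.482444;0.456371;0.486253	1;2;3
60	rs10873998	1p31.1	ADGRL4	intergenic	0.466702	1;2;3;4
61	rs1104918	15q25.3	NTRK3	intron	0.239850;0.19576	1;4
62	rs2310173	2q11.2	IL1R2,IL1R1	intron	0.455849;0.358208	2;3;4
63	rs12871532	13q33.3		intergenic	0.460323;0.454100	1;2;3;4
64	rs609412	5q32	PPP2R2B	intron	0.260245;0.376361;0.355398	1;2;3;4
65	rs360932	4q31.3	RNA5SP169	intron	0.443636;0.437177;0.38767	1;2;3;4
66	rs13418455	2q31.3		intergenic	0.342787;0.283577;0.293173	2;3;4
67	rs3791556	2q37.3	HDAC4	intron	0.163726;0.171291;0.162051	1;2;3;4
68	rs4650608	1p31.1		intergenic	0.280812;0.312248;0.293815	4
69	rs7799006	7p22.3	MRM2	three_prime_UTR	0.353602;0.344482;0.333479	1;2;3
70	rs6990255	8p12	PPP1R3B,RPL10AP3	intron	0.048947;0.100899;0.103487	2;4
71	rs4741652	9p24.3	SMARCA2,RN7SL592P	intergenic	0.218916;0.266060	1;2;3;4
72	rs10994359	10q21.2	ANK3	intron	0.086131;0.077921	1;2;3;4
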