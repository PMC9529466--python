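child	family	gene	hgvs	clinical_significance	consequence	dbsnp_id	maf
AU53	1	GCK	NM_000162.5:c.1018A>G	likely_pathogenic	missense	rs193922255
AU54	1	HOGA1	NM_138413.4:c.769T>G	likely_pathogenic	missense	rs267606764	0.00020
AU209	2	COL3A1	NM_000090.3:c.637G>A	pathogenic	missense	rs587779557
AU209	2	SLC22A5	NM_003060.4:c.287G>C	conflicting	missense	rs377767450	0.00013
AU209	2	KCNQ2	NM_172107.4:c.2245G>T	pathogenic	stop_gained	rs796052658	0.00000
AU209	2	CBS	NM_000071.3:c.457G>A	likely_pathogenic	missense	rs745704046	0.00004
AU210	2	NSD1	NM_022455.4:c.5146+1G>A	likely_pathogenic	splice_donor	rs587784139
AU210	2	PCNT	NM_006031.6:c.5767C>T	likely_pathogenic	stop_gained	rs119479062	0.00001
AU216	4	COL3A1	NM_000090.3:c.2022G>T	pathogenic	missense	rs587779643
AU216	4	KCNH2	NM_172056.2:c.2390C>A	likely_pathogenic	missense	rs794728389
AU216	4	HEPACAM	NM_152722.5:c.740C>T	VUS	missense	rs145619784	0.00020
AU217	4	WNT10A	NM_025216.3:c.1087A>C	conflicting	missense	rs34972707	0.00028
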