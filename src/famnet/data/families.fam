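1 FA1 0 0 1 0
1 MO1 0 0 2 0
1 AU53 FA1 MO1 1 0
1 AU54 FA1 MO1 1 0
1 SIB1 FA1 MO1 2 0
2 FA2 0 0 1 0
2 MO2 0 0 2 0
2 AU209 FA2 MO2 1 0
2 AU210 FA2 MO2 1 0
2 SIB2 FA2 MO2 2 0
3 FA3 0 0 1 0
3 MO3 0 0 2 0
3 AU301 FA3 MO3 1 0
3 AU302 FA3 MO3 1 0
4 FA4A 0 0 1 0
4 FA4B 0 0 1 0
4 MO4 0 0 2 0
4 AU216 FA4A MO4 1 0
4 AU217 FA4B MO4 2 0
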