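carbons	double_bonds
12	0
14	0
14	1
16	0
16	1
17	0
18	0
18	1
18	2
18	3
20	0
20	1
20	2
20	3
20	4
20	5
22	4
22	5
22	6
24	0
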