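class_abbreviation	n_chains	supports_sn
AC	1	0
ChE	1	0
Cer(NS)	2	0
DG	2	0
FA	1	0
HexCer(NS)	2	0
LPA	1	1
LPC	1	1
LPE	1	1
LPG	1	1
LPI	1	1
LPS	1	1
MG	1	1
PA	2	0
PC	2	0
PE	2	0
PG	2	0
PI	2	0
PS	2	0
SM	2	0
TG	3	0
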