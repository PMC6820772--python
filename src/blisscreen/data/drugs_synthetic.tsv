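abbrev	name	targets
PI	PI-103	PIK3CA;PIK3CB;PIK3CD;MTOR;PRKDC
BI	Doramapimod	MAPK14
D1	BI-D1870	RPS6KA1;RPS6KA2;RPS6KA3;RPS6KA6
G2	GSK2334470	PDPK1
JN	JNK-IN-8	MAPK8;MAPK9;MAPK10
PD	PD-0325901	MAP2K1;MAP2K2
5Z	5Z-7-oxozeaenol	MAP3K7
SF	SF1670	PTEN
AK	Akt Inhibitor VIII	AKT1;AKT2;AKT3
P5	P505-15	SYK
RU	Ruxolitinib	JAK1;JAK2
SB	SB-505124	TGFBR1
B6	BI605906	IKBKB
F4	10058-F4	MYC
X1	synthetic inhibitor 1	STAT3
X2	synthetic inhibitor 2	GSK3B
X3	synthetic inhibitor 3	CSNK2A1
X4	synthetic inhibitor 4	CTNNB1
X5	synthetic inhibitor 5	RPS6KB1
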