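number	gene_symbol
1	PTGS2
2	ACHE
3	NOS2
4	PPARG
5	GSK3B
6	NOS3
7	BCL2
8	TNF
9	JUN
10	HMOX1
11	CYP1A2
12	VCAM1
13	AHR
14	INSR
15	GSTM1
16	MAPK1
17	EGF
18	IL6
19	TP53
20	POR
21	SOD1
22	GJA1
23	IL1B
24	COL1A1
25	IFNG
26	MPO
27	NQO1
28	PON1
29	KDR
30	CYCS
31	GSTA1
32	APP
33	MAPK3
34	LDLR
35	CAT
36	HMGCR
37	GSR
38	XDH
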