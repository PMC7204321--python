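mol_id	name	herb	mw	alogp	hdon	hacc	ob	dl
MOL013187	Cubebin	RB	356.4	3.19	1	6	57.13	0.64
MOL004598	3,5,6,7-Tetramethoxy-2-(3,4,5-trimethoxyphenyl)chromone	RB	432.46	2.54	0	9	31.97	0.59
MOL004624	Longikaurin A	RB	348.48	1.16	3	5	47.72	0.53
MOL004609	Areapillin	RB	360.34	2.29	3	8	48.96	0.41
MOL000354	Isorhamnetin	RB	316.28	1.76	4	7	49.6	0.31
MOL000490	Petunidin	RB	317.29	1.65	5	7	30.05	0.31
MOL000098	Quercetin	RB	302.25	1.5	5	7	46.43	0.28
MOL000422	Kaempferol	RB	286.25	1.77	4	6	41.88	0.24
MOL001458	Coptisine	SR	320.34	3.25	0	4	30.67	0.86
MOL002897	Epiberberine	SR	336.39	3.45	0	4	43.09	0.78
MOL002909	5,7,2,5-Tetrahydroxy-8,6-dimethoxyflavone	SR	376.34	2.02	4	9	33.82	0.45
MOL002934	Neobaicalein	SR	374.37	2.54	2	8	104.34	0.44
MOL002927	Skullcapflavone II	SR	374.37	2.54	2	8	69.51	0.44
MOL012266	Rivularin	SR	344.34	2.55	2	7	37.94	0.37
MOL000552	5,2'-Dihydroxy-6,7,8-trimethoxyflavone	SR	344.34	2.55	2	7	31.71	0.35
MOL002915	Salvigenin	SR	328.34	2.82	1	6	49.07	0.33
MOL002917	5,2',6'-Trihydroxy-7,8-dimethoxyflavone	SR	330.31	2.3	3	7	45.05	0.33
MOL002932	Panicolin	SR	314.31	2.57	2	6	76.26	0.29
MOL012245	5,7,4'-Trihydroxy-6-methoxyflavanone	SR	302.3	2.28	3	6	36.63	0.27
MOL002933	5,7,4'-Trihydroxy-8-methoxyflavone	SR	300.28	2.32	3	6	36.56	0.27
MOL012246	5,7,4'-Trihydroxy-8-methoxyflavanone	SR	302.3	2.28	3	6	74.24	0.26
MOL008206	Moslosooflavone	SR	298.31	2.84	1	5	44.09	0.25
MOL002914	Eriodictyol (flavanone)	SR	288.27	2.03	4	6	41.35	0.24
MOL002910	Carthamidin	SR	288.27	2.03	4	6	41.15	0.24
MOL002925	5,7,2',6'-Tetrahydroxyflavone	SR	286.25	2.07	4	6	37.01	0.24
MOL001689	Acacetin	SR	284.28	2.59	2	5	34.97	0.24
MOL002937	Dihydrooroxylin	SR	286.3	2.55	2	5	66.06	0.23
MOL002928	Oroxylin A	SR	284.28	2.59	2	5	41.37	0.23
MOL000173	Wogonin	SR	284.28	2.59	2	5	30.68	0.23
MOL002913	Dihydrobaicalin_qt	SR	272.27	2.3	3	5	40.04	0.21
MOL000525	Norwogonin	SR	270.25	2.33	3	5	39.4	0.21
MOL002714	Baicalein	SR	270.25	2.33	3	5	33.52	0.21
MOL000228	(2R)-7-Hydroxy-5-methoxy-2-phenylchroman-4-one	SR	270.3	2.82	1	4	55.23	0.2
MOL001002	Ellagic acid	RPR	302.2	1.48	4	8	43.06	0.43
MOL001918	Paeoniflorgenone	RPR	318.35	0.79	1	6	87.59	0.37
MOL006992	(2R,3R)-4-Methoxyl-distylin	RPR	318.3	1.89	4	7	59.98	0.3
MOL002714	Baicalein	RPR	270.25	2.33	3	5	33.52	0.21
MOL002670	Cavidine	ATT	353.45	3.72	0	5	35.64	0.81
MOL006957	(3S,6S)-3-(Benzyl)-6-(4-hydroxybenzyl)piperazine-2,5-quinone	ATT	310.38	2.15	3	5	46.89	0.27
MOL006967	Beta-D-Ribofuranoside, xanthine-9	ATT	284.26	-1.29	5	9	44.72	0.21
MOL002714	Baicalein	ATT	270.25	2.33	3	5	33.52	0.21
MOL005828	Nobiletin	AFI	402.43	3.04	0	8	61.67	0.52
MOL001803	Sinensetin	AFI	372.4	3.06	0	7	50.56	0.45
MOL013277	Isosinensetin	AFI	372.4	3.06	0	7	51.15	0.44
MOL009053	4-[(2S,3R)-5-[(E)-3-Hydroxyprop-1-enyl]-7-methoxy-3-methylol-2,3-dihydrobenzofuran-2-yl]-2-methoxy-phenol	AFI	358.42	2.16	3	6	50.76	0.39
MOL007879	Tetramethoxyluteolin	AFI	342.37	3.07	0	6	43.68	0.37
MOL013435	Poncimarin	AFI	330.41	2.74	0	5	63.62	0.35
MOL013436	Isoponcimarin	AFI	330.41	2.94	0	5	63.28	0.31
MOL013279	5,7,4'-Trimethylapigenin	AFI	312.34	3.09	0	5	39.83	0.3
MOL013430	Prangenin	AFI	286.3	2.49	0	5	43.6	0.29
MOL001798	Neohesperidin_qt	AFI	302.3	2.28	3	6	71.17	0.27
MOL005100	5,7-Dihydroxy-2-(3-hydroxy-4-methoxyphenyl)chroman-4-one	AFI	302.3	2.28	3	6	47.74	0.27
MOL000006	Luteolin	AFI	286.25	2.07	4	6	36.16	0.25
MOL002914	Eriodictyol (flavanone)	AFI	288.27	2.03	4	6	41.35	0.24
MOL005849	Didymin	AFI	286.3	2.55	2	5	38.55	0.24
MOL001941	Ammidin	AFI	270.3	3.65	0	4	34.55	0.22
MOL004328	Naringenin	AFI	272.27	2.3	3	5	59.29	0.21
MOL002235	Eupatin	RERR	360.34	1.99	3	8	50.8	0.41
MOL002268	Rhein	RERR	284.23	1.88	3	6	47.07	0.28
MOL000471	Aloe-emodin	RERR	270.25	1.67	3	5	83.38	0.24
MOL000096	(-)-Catechin	RERR	290.29	1.92	5	6	49.68	0.24
MOL002281	Toralactone	RERR	272.27	2.25	2	5	46.46	0.24
MOL006129	6-Methylgingediacetate2	ZOR	394.56	4.55	0	6	48.73	0.32
MOL000787	Fumarine	JF	353.4	2.95	0	6	59.26	0.83
MOL001454	Berberine	JF	336.39	3.45	0	4	36.86	0.78
MOL004350	Ruvoside_qt	JF	390.57	2.29	3	5	36.12	0.76
MOL012986	Jujubasaponin V_qt	JF	472.78	4.65	2	4	36.99	0.63
MOL012946	Ziziphus saponin I_qt	JF	472.78	4.39	2	4	32.69	0.62
MOL000627	Stepholidine	JF	327.41	3.1	2	5	33.11	0.54
MOL012992	Mauritine D	JF	342.46	1.62	2	6	89.13	0.45
MOL007213	Nuciferine	JF	295.41	3.57	0	3	34.43	0.4
MOL012976	Coumestrol	JF	268.23	3.01	2	5	32.49	0.34
MOL012921	Stepharine	JF	297.38	1.82	1	4	31.55	0.33
MOL001522	(S)-coclaurine	JF	285.37	2.83	3	4	42.35	0.24
MOL000098	Quercetin	JF	302.25	1.5	5	7	46.43	0.28
MOL000492	(+)-Catechin	JF	290.29	1.92	5	6	54.83	0.24
MOL000096	(-)-Catechin	JF	290.29	1.92	5	6	49.68	0.24
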