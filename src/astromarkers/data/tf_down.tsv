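SYMBOL	LONZA_FET_AST	SCIENCELL_FET_AST	NCRM5_NSC	H9_NSC
ARID3B	72	33	431	737
CBX2	155	80	695	494
CHD7	277	388	2277	1863
CHX10	1	16	204	108
CXXC4	51	51	827	287
CXXC6	17	26	200	220
E2F2	210	301	1064	834
EBF1	19	1	146	146
ETV4	36	54	217	143
EZH2	204	253	740	533
FLI1	32	13	177	501
GLI2	71	48	189	176
H1FX	268	297	629	606
HES6	551	527	3211	1653
HIC2	153	77	800	1039
IRX2	70	23	410	2254
IRX5	48	29	458	342
KNTC1	372	473	1495	1122
LIN28	1	1	276	1218
LIN28B	1	6	649	1955
MYCN	74	90	1299	785
MYST3	643	621	1624	1489
PBX2	104	144	327	299
PHF16	106	101	350	332
PKNOX2	141	102	751	304
PLAGL2	182	237	536	532
POU3F2	839	944	3439	2596
PRDM8	22	36	2559	108
RAPGEF5	22	17	146	108
RCOR2	57	43	1187	663
SALL2	597	541	2225	1498
SALL4	39	17	458	1024
SORBS2	176	177	1337	2257
SOX3	351	75	3147	1629
STAT5B	75	44	151	172
SUV420H1	140	111	307	285
TCF7L1	13	17	184	104
TRIT1	382	380	879	857
ZBTB34	53	47	174	175
ZBTB39	41	22	116	85
ZBTB46	56	3	263	350
ZFHX3	181	212	479	745
ZFP14	26	5	108	52
ZMYND8	114	114	415	361
ZNF138	33	34	114	96
ZNF219	157	193	987	761
ZNF431	47	30	108	95
ZNF443	30	44	138	105
ZNF462	429	402	1759	1220
ZNF679	450	425	1167	1551
ZNF696	115	83	256	266
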