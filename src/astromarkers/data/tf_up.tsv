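SYMBOL	LONZA_FET_AST	SCIENCELL_FET_AST	NCRM5_NSC	H9_NSC
BCL6	280	406	54	24
BHLHB2	1233	1069	114	1
BHLHB3	145	187	2	1
CSDC2	425	189	33	21
CXXC5	3189	1658	625	715
DPF3	267	149	11	1
EGR1	3970	3779	1197	443
EMX2	763	311	11	4
ETS2	207	114	23	24
FOS	606	3343	198	63
FOXG1	547	1021	1	14
GLIPR1	850	854	4	64
GLIS3	162	157	68	48
GTF2F2	4033	3423	1437	1564
HEY1	727	805	114	29
HOPX	1309	1417	210	1
ID1	708	389	166	8
IRF9	1394	735	260	168
JUN	2010	1435	605	672
KLF5	165	275	14	7
KLF6	874	879	302	406
KLF9	724	616	132	2
LHX2	4177	4542	2	16
MBNL1	370	504	114	159
NFE2L3	705	200	44	93
NFIA	335	343	80	1
NFIB	5565	3405	1012	287
NFIC	242	175	9	7
NFIX	4122	1730	4	1
NR2E1	529	776	13	8
OTX1	183	100	1	10
PRDM16	161	113	8	3
PRRX1	286	828	1	4
RBM20	133	320	62	12
RUNX2	157	169	29	67
ZBTB20	450	943	72	81
ZBTB4	824	818	303	275
ZC3HAV1	312	291	135	121
ZFP3	202	212	19	9
ZFP36	218	333	69	102
ZNF135	368	216	41	38
ZNF385D	387	101	39	2
PHF11	638	512	9	2
PHF15	152	199	18	7
SETD6	196	129	16	23
SMARCA2	897	1052	238	188
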