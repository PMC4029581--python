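SYMBOL	LONZA_FET_AST	SCIENCELL_FET_AST	NCRM5_NSC	H9_NSC
BEND6	216	308	3	10
CD44	3920	4352	145	233
CDKN2B	1141	440	13	17
COBL	100	399	17	7
CRYAB	1305	1230	7	1
DUSP23	1004	432	11	11
GFAP	3280	1456	8	1
HEY1	727	805	114	29
HOPX	1309	1417	210	1
IGFBP7	1487	1623	31	18
ITGA3	1056	1039	88	88
LGALS3	3055	1599	52	2
LHX2	4177	4542	2	16
LMO2	360	1674	6	1
LPPR4	431	537	1	1
MVP	266	323	16	6
NFIX	4122	1730	4	1
PRRX1	286	828	1	4
S100A6	3500	2917	40	28
SLC25A18	623	303	4	5
SYNC1	1084	395	32	8
TDRD7	264	292	5	8
TGFB3	959	156	15	10
TM4SF1	643	589	20	105
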