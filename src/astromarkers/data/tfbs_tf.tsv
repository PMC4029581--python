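SYMBOL	LONZA_FET_AST	SCIENCELL_FET_AST	NCRM5_NSC	H9_NSC
ATF1	180	205	151	268
CREB1	1272	1269	1593	1619
E2F2	210	301	1064	834
E2F3	884	1095	1633	1570
EGR1	3970	3779	1197	443
GABPA	130	137	184	121
HBP1	319	177	220	170
LEF1	1122	219	6	222
NFIC	242	175	9	7
NFKB1	1176	684	591	878
RXRA	379	291	464	446
SMAD3	1171	444	687	611
SP1	232	302	387	343
SRF	1655	843	1415	1051
STAT1	703	627	487	353
STAT3	538	369	491	399
TCF3	622	819	1309	1159
TCF7L2	133	182	267	269
TGIF1	221	182	247	258
ZFP161	285	132	371	336
ZNF187	191	161	142	102
ZNF281	457	703	707	924
ZNF410	756	665	775	742
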