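cluster_id	representative_id	n_members
1	CD28_1yjdC_human_V	11
2	B2Microglobulin_7phrL_human_C1	8
3	BTLA_2aw2A_human_Iset	6
4	CD19_6al5A_human_C2orV-n1	3
5	Contactin1_2ee2A_human_FN3-n9	8
6	C3_2qkiD_human_n1	2
7	ECadherin_4zt1A_human_n2	1
8	NaKATPaseTransporterBeta_2zxeB_spurdogshark	1
9	RBPJ_6py8C_human_Unk-n1	2
10	ASF1A_2iijA_human	2
11	BArrestin1_4jqiA_rat_n1	2
12	LaminAC_1ifrA_human	1
13	CoAtomerGamma1_1r4xA_human	2
14	CuZnSuperoxideDismutase_1hl5C_human	3
15	VISTA_6oilA_human_V	1
16	ORF7a_1xakA_virus	2
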