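template_id	protein	ig_type	template_class	scop	pdb_id	chain	cluster_id	topology	comment
CD2_1hnfA_human_V-n1	CD2	IgV	Ig	b.1.1.1	1hnf	A	1	igv	
CD28_1yjdC_human_V	CD28	IgV	Ig	b.1.1.1	1yjd	C	1	igv	
CD8a_1cd8A_human_V	CD8a	IgV	Ig	b.1.1.1	2atp	A	1	igv	
FAB-HEAVY_5esv_V-n1	FAB-VH	IgV	Ig	b.1.1.1	5esv	C	1	igv	
FAB-LIGHT_5esv_V-n1	FAB-VL	IgV	Ig	b.1.1.1	5esv	D	1	igv	
ICOS_6x4gA_human_V	CD278 (ICOS)	IgV	Ig	b.1.1.1	6x4g	A	1	igv	
LAG3_7tzgD_human_V-n1	LAG3	IgV	Ig	Unk.	7tzg	D	1	igv	
PD1_4zqkB_human_V	CD279 (PD1)	IgV	Ig	b.1.1.1	4zqk	B	1	igv	
PDL1_4z18B_human_V-n1	CD274 (PDL1)	IgV	Ig	b.1.1.1	4z18	B	1	igv	
VNAR_1t6vN_shark_V	VNAR	IgV	Ig	b.1.1.1	1t6v	N	1	igv	
Zuppl_IgV_synth	synthetic V-set supplement	IgV	Ig	n/a			1	igv	supplement
B2Microglobulin_7phrL_human_C1	B2-Microglobulin	IgC1	Ig	b.1.1.2	7phr	L	2	igc1	
CD3d_6jxrd_human_C1	CD3d	IgC1	Ig	b.1.1.4	6jxr	d	2	igc1	
CD3e_6jxrf_human_C1	CD3e	IgC1	Ig	b.1.1.4	6jxr	f	2	igc1	
FAB-HEAVY_5esv_C1-n2	FAB-CH1	IgC1	Ig	b.1.1.2	5esv	C	2	igc1	
FAB-LIGHT_5esv_C1-n2	FAB-CL1	IgC1	Ig	b.1.1.2	5esv	D	2	igc1	
LAG3_7tzgD_human_C2-n2	LAG3	IgC1	Ig	Unk.	7tzg	D	2	igc1	
MHCIa_7phrH_human_C1	MHCI alpha	IgC1	Ig	b.1.1.2	7phr	H	2	igc1	
Siglec3_5j0bB_human_C1-n2	Siglec-3 CD33	IgC1	Ig	Unk.	5j0b	B	2	igc1	
BTLA_2aw2A_human_Iset	BTLA	IgI	Ig	b.1.1.4	2aw2	A	3	igi	
Contactin1_3s97C_human_Iset-n2	Contactin1	IgI	Ig	b.1.1.0	3s97	C	3	igi	
JAM1_1nbqA_human_Iset-n2	JAM1	IgI	Ig	b.1.1.4	1nbq	A	3	igi	
Palladin_2dm3A_human_Iset-n1	Palladin	IgI	Ig	b.1.1.4	2dm3	A	3	igi	
Titin_4uowM_human_Iset-n152	Titin	IgI	Ig	Unk.	4uow	M	3	igi	
Zuppl_IgI_synth	synthetic I-set supplement	IgI	Ig	n/a			3	igi	supplement
CD19_6al5A_human_C2orV-n1	CD19	other-Ig	Ig	Unk.	6al5	A	4	igc2	
CD2_1hnfA_human_C2-n2	CD2	IgC2	Ig	b.1.1.3	1hnf	A	4	igc2	
CD3g_6jxrg_human_C2	CD3g	IgC2	Ig	b.1.1.4	6jxr	g	4	igc2_gplus	G+ strand
Contactin1_2ee2A_human_FN3-n9	Contactin1	IgFN3	Ig-like	b.1.2.0	2ee2	A	5	fn3	
GHR_1axiB_human_FN3-n1	GHR	IgFN3	Ig-like	b.1.2.1	1axi	B	5	fn3	
IL6Rb_1bquB_human_FN3-n2	CD130 (IL6R-beta)	IgFN3	Ig-like	b.1.2.1	1bqu	B	5	fn3	
IL6Rb_1bquB_human_FN3-n3	CD130 (IL6R-beta)	IgFN3	Ig-like	b.1.2.1	1bqu	B	5	fn3	
InsulinR_8guyE_human_FN3-n1	Insulin Receptor	IgFN3	Ig-like	b.1.2.1	8guy	E	5	fn3	
InsulinR_8guyE_human_FN3-n2	Insulin Receptor	IgFN3	Ig-like	b.1.2.1	8guy	E	5	fn3	
Sidekick2_1wf5A_human_FN3-n7	Sidekick-2	IgFN3	Ig-like	b.1.2.1	1wf5	A	5	fn3	
Zuppl_FN3_synth	synthetic FN3 supplement	IgFN3	Ig-like	n/a			5	fn3	supplement
C3_2qkiD_human_n1	C3 Complement	IgFN3-like	Ig-like	b.1.29.2	2qki	D	6	fn3_like	
NaCaExchanger_2fwuA_dog_n2	NaCa Exchanger	IgFN3-like	Ig-like	b.1.27.1	2fwu	A	6	fn3_like	
ECadherin_4zt1A_human_n2	E-Cadherin	other-Ig	Ig-like	b.1.6.1	4zt1	A	7	cadherin	
NaKATPaseTransporterBeta_2zxeB_spurdogshark	NaK ATPase Transporter-Beta	other-Ig	Ig-like	b.1.32.1	2zxe	B	8	igc1_short	
RBPJ_6py8C_human_Unk-n1	RBPJ	other-Ig	Ig-like	Unk.	6py8	C	9	sandwich_min	
RBPJ_6py8C_human_Unk-n2	RBPJ	other-Ig	Ig-like	Unk.	6py8	C	9	sandwich_min	
ASF1A_2iijA_human	ASF-1A Histone Chaperone	IgFN3-like	Ig-extended	b.1.22.1	2iij	A	10	barrel_wide	
MPT63_1lmiA_bacteria	MPT63	IgFN3-like	Ig-extended	b.1.19.1	1lmi	A	10	barrel_wide	
BArrestin1_4jqiA_rat_n1	B-Arrestin-1	IgFN3-like	Ig-extended	b.1.18.11	4jqi	A	11	arrestin	A-/E+ strands
TEAD1_3kysC_human	TEAD1 (TEF1)	IgFN3-like	Ig-extended	b.1.18.26	3kys	C	11	arrestin	
LaminAC_1ifrA_human	Lamin-A/C	other-Ig	Ig-extended	b.1.16.1	1ifr	A	12	lamin	A- strand 14xx
CoAtomerGamma1_1r4xA_human	CoAtomer-Gamma-1	other-Ig	Ig-extended	b.1.10.3	1r4x	A	13	ext_twist	
Endo-14-BetaXylanase10A_1i8aA_bacteria_n4	Endo-1,4-Beta-Xylanase-A	other-Ig	Ig-extended	b.1.9.2	1i8a	A	13	ext_twist	
CuZnSuperoxideDismutase_1hl5C_human	CuZn Superoxide Dismutase	IgFN3-like	Ig-extended	b.1.8.2	1hl5	C	14	ext_neat	
IsdA_2iteA_bacteria	IsdA NEAT domain	other-Ig	Ig-extended	b.1.28.1	2ite	A	14	ext_neat	A- strand
TP34_2o6cA_bacteria	TP34	other-Ig	Ig-extended	b.1.33.1	2o6c	A	14	ext_neat	
VISTA_6oilA_human_V	VISTA (VSIR)	IgV	Ig-extended	b.1.1.1	6oil	A	15	ext_gplus	A-/G+ strands
ORF7a_1xakA_virus	ORF7a	other-Ig	Ig-like	b.1.24.1	1xak	A	16	ext_full	
TP47_1o75A_bacteria	Tp47 Lipoprotein	other-Ig	Ig-like	b.1.20.1	1o75	A	16	ext_full	
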