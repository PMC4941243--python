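snp_id	gene	alleles	cluster_size_mm3	x	y	z	peak_f	label	abbrev	hemisphere	pass_S	pass_SG
rs2230806	ABCA1	AG	2214	-21	-102	9	12.70	Middle Occipital Gyrus_L	L.MOG	L	1	0
rs2230806	ABCA1	AG	2241	-15	30	33	9.96	Middle Frontal Gyrus_L	L.MFG	L	1	0
rs2230806	ABCA1	AG	1539	0	-57	0	9.95	Vermis_4_5	Vermis45	V	1	0
rs7412	APOE	CT	2079	-42	27	24	19.15	Inferior Frontal Gyrus_L	L.IFG	L	1	0
rs7412	APOE	CT	2025	-60	-33	-15	15.59	Middle Temporal Gyrus_L	L.MTG	L	1	0
rs7412	APOE	CT	2403	33	-9	15	14.79	Insula_R	R.INS	R	1	0
rs7412	APOE	CT	1809	15	-24	39	14.40	Middle Cingulum Gyrus_R	R.MCG	R	1	0
rs429358	APOE	CT	2349	-36	-57	-33	81.78	Cerebellum Posterior Lobe_L	L.CRBL_Po	L	1	1
rs429358	APOE	CT	1485	36	15	-36	66.04	Superior Temporal Gyrus_R	R.STG	R	1	1
rs429358	APOE	CT	2538	-3	21	18	38.42	Anterior Cingulate Gyrus_L	L.ACG	L	1	0
rs429358	APOE	CT	1998	-12	-45	-3	31.11	Parahippocampal gyrus_L	L.PHG	L	1	0
rs440446	APOE	CG	2754	15	-48	51	21.37	Precuneus_R	R.PCUN	R	1	0
rs440446	APOE	CG	2133	-21	-51	-36	21.34	Cerebellum Anterior Lobe_L	L.CRBL_Ant	L	1	0
rs440446	APOE	CG	3159	21	-57	-39	17.91	Cerebellum Posterior Lobe_R	R.CRBL_Po	R	1	0
rs440446	APOE	CG	1431	-57	-66	9	15.37	Middle Temporal Gyrus_L	L.MTG	L	1	0
rs4417181	CH25H	CT	1809	39	30	15	15.37	Middle Frontal Gyrus_R	R.MFG	R	1	0
rs754203	CYP1	CT	2916	30	27	-15	17.80	Inferior Frontal Gyrus_R	R.IFG	R	1	0
rs754203	CYP1	CT	2079	36	-12	-27	15.94	Parahippocampal gyrus_R	R.PHG	R	1	0
rs7157609	CYP1	AC	2565	30	27	-15	15.00	Inferior Frontal Gyrus_R	R.IFG	R	1	0
rs7157609	CYP1	AC	2106	33	-12	-27	14.87	Parahippocampal gyrus_R	R.PHG	R	1	0
rs1433099	LDLR	AG	1296	3	21	48	16.18	Medial Frontal Gyrus_R	R.MeFG	R	1	0
rs2738444	LDLR	CT	5940	45	-36	42	28.40	Inferior Parietal Lobule_R	R.IPL	R	1	1
rs1799986	LRP1	CT	1620	69	-27	-21	16.63	Inferior Temporal Gyrus_R	R.ITG	R	1	0
rs5177	LRP8	CG	3780	48	9	39	27.68	Middle Frontal Gyrus_R	R.MFG	R	1	0
rs5177	LRP8	CG	4698	30	24	18	18.91	Insula_R	R.INS	R	1	0
rs5177	LRP8	CG	4779	36	-24	54	17.88	Precentral Gyrus_R	R.PreCG	R	1	0
rs5177	LRP8	CG	4131	-9	36	-15	16.36	Medial Frontal Gyrus_B	B.MeFG	B	1	0
rs3737983	LRP8	CT	1296	18	36	51	14.93	Superior Frontal Gyrus_R	R.SFG	R	1	0
rs3820198	LRP8	GT	3483	-30	6	3	14.34	Putamen_L	L.Put	L	1	0
rs1801133	MTHFR	CT	1404	-24	-84	15	8.49	Middle Occipital Gyrus_L	L.MOG	L	1	0
rs3753526	SOAT1	CG	2916	-39	27	3	22.29	Inferior Frontal Gyrus_L	L.IFG	L	1	0
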