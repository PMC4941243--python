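snp_id	gene	alleles
rs2230806	ABCA1	AG
rs7412	APOE	CT
rs405509	APOE	AC
rs429358	APOE	CT
rs440446	APOE	CG
rs769450	APOE	AG
rs4417181	CH25H	CT
rs7091822	CH25H	GT
rs17117126	CH25H	AG
rs2424577	CST3	AG
rs3827143	CST3	AG
rs754203	CYP1	CT
rs4900442	CYP1	CT
rs7157609	CYP1	AC
rs3758505	IDE	GT
rs4646954	IDE	AG
rs688	LDLR	CT
rs5925	LDLR	CT
rs1433099	LDLR	AG
rs2738444	LDLR	CT
rs11668477	LDLR	AG
rs12983082	LDLR	AC
rs1140648	LRP1	AG
rs1799986	LRP1	CT
rs2306692	LRP1	CT
rs5177	LRP8	CG
rs3737983	LRP8	CT
rs3820198	LRP8	GT
rs1801133	MTHFR	CT
rs2227564	PLAU	CT
rs1044925	SOAT1	AC
rs2862616	SOAT1	CT
rs3753526	SOAT1	CG
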