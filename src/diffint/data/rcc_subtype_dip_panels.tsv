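subtype	protein	secreted
ccRCC	ABCC2	1
ccRCC	B2M	1
ccRCC	BST2	1
ccRCC	CALU	1
ccRCC	CCDC106	1
ccRCC	CENPA	1
ccRCC	CYB5R3	1
ccRCC	DDX3X	1
ccRCC	DKC1	1
ccRCC	DNAJB4	1
ccRCC	DTNBP1	1
ccRCC	GABBR1	1
ccRCC	GIT2	1
ccRCC	HLA-B	1
ccRCC	HSPBP1	1
ccRCC	IMMT	1
ccRCC	MAPK3	1
ccRCC	NRP1	1
ccRCC	PDIA4	1
ccRCC	PEA15	1
ccRCC	PFDN2	1
ccRCC	PFKM	1
ccRCC	PPIB	1
ccRCC	PRKCD	1
ccRCC	RGCC	1
ccRCC	RPS6KA3	1
ccRCC	SDHA	1
ccRCC	UBQLN1	1
ccRCC	TNIP1	1
ccRCC	AZIN1	0
ccRCC	CDT1	0
ccRCC	ELF4	0
ccRCC	FBXW8	0
ccRCC	GPS2	0
ccRCC	IL32	0
ccRCC	IRF1	0
ccRCC	LDOC1	0
ccRCC	MCM7	0
ccRCC	MCM9	0
ccRCC	MTF1	0
ccRCC	MTOR	0
ccRCC	P4HA2	0
ccRCC	PHLPP1	0
ccRCC	RSL1D1	0
ccRCC	SCD	0
ccRCC	TAF1	0
ccRCC	TAPBP	0
ccRCC	TOMM20	0
ccRCC	USP2	0
ccRCC	ZNF668	0
pRCC	CS	1
pRCC	CUL3	1
pRCC	DFFA	1
pRCC	DHFR	1
pRCC	EIF4A2	1
pRCC	FLOT2	1
pRCC	G6PD	1
pRCC	GSTA2	1
pRCC	IGBP1	1
pRCC	ITGA3	1
pRCC	MET	1
pRCC	MME	1
pRCC	MVP	1
pRCC	PARP4	1
pRCC	PGM2	1
pRCC	PNPT1	1
pRCC	PPM1A	1
pRCC	TRAPPC1	1
pRCC	GSTA4	0
pRCC	HGF	0
pRCC	LBH	0
pRCC	LGALS8	0
pRCC	MMGT1	0
pRCC	RANBP9	0
pRCC	SF3A3	0
pRCC	SOCS1	0
pRCC	TRAPPC12	0
pRCC	TRAPPC2L	0
pRCC	UNG	0
chRCC	ANXA5	1
chRCC	AQP1	1
chRCC	ARF1	1
chRCC	BAD	1
chRCC	CHMP4B	1
chRCC	CYLD	1
chRCC	ECH1	1
chRCC	EEF1B2	1
chRCC	FLOT1	1
chRCC	FUS	1
chRCC	HADHA	1
chRCC	HADHB	1
chRCC	HSD17B10	1
chRCC	JUP	1
chRCC	KRT18	1
chRCC	MAPRE1	1
chRCC	PARK7	1
chRCC	PFN1	1
chRCC	PHB	1
chRCC	PHB2	1
chRCC	PPP1CB	1
chRCC	PRDX1	1
chRCC	PRDX2	1
chRCC	PRDX3	1
chRCC	PRDX5	1
chRCC	PSMB4	1
chRCC	PSMB6	1
chRCC	PSME1	1
chRCC	PTGES3	1
chRCC	PTMA	1
chRCC	RAB1A	1
chRCC	RAB7A	1
chRCC	S100A10	1
chRCC	TGOLN2	1
chRCC	TXN	1
chRCC	UBB	1
chRCC	UBE3A	1
chRCC	YWHAB	1
chRCC	YWHAE	1
chRCC	ABL1	0
chRCC	AMFR	0
chRCC	ARAF	0
chRCC	CDK9	0
chRCC	FOS	0
chRCC	JUND	0
chRCC	MCL1	0
chRCC	MORF4L2	0
chRCC	SF3B5	0
chRCC	STAU1	0
chRCC	TRIM8	0
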