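aDC	immune_cell_type	CCL1	CCL19	CD83	EBI3	IDO1	LAMP3	OAS3
B cells	immune_cell_type	ABCB4	BACH2	BCL11A	BLK	BLNK	CCR9	CD19	CD38	CD72	CD79A	CD79B	COCH	CR2	DTNB	FCRL2	FCRLA	GLDC	GNG7	HLA-DOB	IGHA1	IGHG1	IGHM	IGKC	KIAA0125	MEF2C	MICAL3	MS4A1	OSBPL10	PNOC	QRSL1	SCN3A	SLC15A2	SPIB	TCL1A	TLR10	TNFRSF17
CD8 T cells	immune_cell_type	ABT1	AES	APBA2	ARHGAP8	C19orf6	C4orf15	CAMLG	CD8A	CD8B	CDKN2AIP	DNAJB1	DNAJB6	FLT3LG	GADD45A	GZMM	KLF9	LEPROTL1	LIME1	MYST3	PF4	PPP1R2	PRF1	PRR5	RBM3	SF1	SFRS7	SLC16A7	TBCC	THUMPD1	TMC6	TSC22D3	VAMP2	ZEB1	ZFP36L2	ZNF22	ZNF609	ZNF91
Cytotoxic cells	immune_cell_type	APBA2	APOL3	CCL4	CTSW	DUSP2	FASLG	GNLY	GZMA	GZMH	KLRB1	KLRD1	KLRF1	KLRG1	KLRK1	NKG7	RORA	RUNX3	SIGIRR	WHAMMP3	ZBTB16
DC	immune_cell_type	CCL13	CCL17	CCL22	CD209	CLIC2	HSD11B1	ITGAX	NPR1	PPFIBP2
Eosinophils	immune_cell_type	ABHD2	ACACB	CAT	CCR3	CLC	CYSLTR2	EMR1	EPN2	EPX	GALC	GPR44	HES1	HIST1H1C	HRH4	IL5RA	KBTBD11	KCNH2	LRP5L	MYO15B	RCOR3	RNASE2	RNASE3	RRP12	SIGLEC8	SMPD3	SYNJ1	TGIF1	THBS1	THBS4	TIPARP
iDC	immune_cell_type	ABCG2	BLVRB	CARD9	CD1A	CD1B	CD1C	CD1D	CD1E	CD207	CH25H	CLEC10A	CSF1R	CTNS	F13A1	FABP4	FZD2	GSTT1	HS3ST2	MMP12	NDRG2	NUDT9	PPARG	PREP	SLC26A6	SLC7A8	SYT17	TACSTD2	TM7SF4	VASH1
Macrophages	immune_cell_type	APOE	ATG7	BCAT1	CCL7	CD163	CD68	CD84	CHI3L1	CHIT1	CLEC5A	COL8A2	COLEC12	CTSK	CXCL5	CYBB	DNASE2B	EMP1	FDX1	FN1	GM2A	GPC4	KAL1	MARCO	ME1	MS4A4A	MSR1	PCOLCE2	PTGDS	RAI14	SCARB2	SCG5	SGMS1	SULT1C2
Mast cells	immune_cell_type	ABCC4	ADCYAP1	CALB2	CEACAM8	CMA1	CPA3	CTSG	ELA2	GATA2	GPR44	HDC	HPGD	HPGDS	KIT	MAOB	MLPH	MPO	MS4A2	NR0B1	PPM1H	PRG2	PTGS1	RAB27B	SCG2	SIGLEC6	SLC18A2	SLC24A3	TAL1	TPSAB1	TPSB2	VWA5A
Neutrophils	immune_cell_type	ALPL	BST1	CD93	CDA	CEACAM3	CREB5	CRISPLD2	CSF3R	CYP4F3	DYSF	FCAR	FCGR3B	FPR1	FPR2	G0S2	HIST1H2BC	HPSE	IL8RA	IL8RB	KCNJ15	LILRB2	MGAM	MME	ORM1	PDE4B	S100A12	SIGLEC5	SLC22A4	SLC25A37	TECPR2	TNFRSF10C	VNN3
NK CD56bright cells	immune_cell_type	DUSP4	FOXJ1	MADD	MPPED1	MUC3B	NCAM1	PLA2G6	RRAD	RRAS2	XCL1
NK CD56dim cells	immune_cell_type	GTF3C1	GZMA	GZMB	IL21R	KIR2DL3	KIR2DS1	KIR2DS2	KIR2DS5	KIR3DL1	KIR3DL2	KIR3DL3	KIR3DS1	S1PR5	SPON2
NK cells	immune_cell_type	ADARB1	ALDH1B1	BCL2	CDC5L	EOMES	FCGR3A	FGF18	FUT5	FZR1	GZMK	IGFBP5	IL18RAP	KLRC3	MAPRE3	MCM3AP	MRC2	NCR1	NCR3	NKTR	PDLIM4	PRX	PSMD4	PTGDR	SH2D1B	SLAMF7	SLC30A5	SPN	TBXA2R	TCTN2	TINAGL1	XCL1	XCL2	ZNF205	ZNF528	ZNF747
pDC	immune_cell_type	IL3RA
T cells	immune_cell_type	CD2	CD247	CD27	CD28	CD3D	CD3E	CD3G	CD6	CD7	CD96	GIMAP5	ITM2A	LAT	LCK	NCALD	PRKCQ	SH2D1A	SKAP1	TRA@	TRAT1	TRBC1
T helper cells	immune_cell_type	ANP32B	ASF1A	ATF2	BATF	BORA	CHD7	DDX50	FAM111A	FRYL	GOLGA8A	ICOS	ITM2A	LRBA	NAP1L4	NUP107	OXNAD1	PHF10	PPP2R5C	SEC24C	SLC25A12	SRSF10	TRA@	UBE2L3	YME1L1
T central memory	immune_cell_type	AQP3	ATF7IP	ATM	CASP8	CDC14A	CLUAP1	CREBZF	CYLD	DOCK9	FAM153B	FOXP1	FYB	HNRPH1	INPP4B	KLF12	MAP3K1	MLL	NEFL	NFATC3	PCM1	PCNX	PHC3	POLR3E	PSPC1	REPS1	RPP38	SLC7A6	SNRPN	ST3GAL1	STX16	SUSD3	TIMM8A	TRAF3IP3	TXK	USP9Y
T effector memory	immune_cell_type	AKT3	CAMK4	CCR2	DDX17	EWSR1	FAS	FLI1	GDPD5	LTK	MEFV	NFATC4	NPAS2	PRKY	SLFN11	TBC1D5	TBCD	VIL2
T follicular helper	immune_cell_type	B3GAT1	BLR1	CDK5R1	CHGB	CHI3L2	HEY1	HIST1H4K	ICA1	KCNK5	KIAA1324	MAF	MAGEH1	MKL2	MYO6	MYO7A	PASK	PDCD1	POMT1	PTPN13	PVALB	SH3TC1	SIRPG	SLC7A10	SMAD1	ST6GALNAC1	ST8SIA1	STK39	THADA	TOX	TSHR	ZNF764
T gamma delta	immune_cell_type	C1orf61	CD160	FEZ1	TARP	TRD@	TRGV9
Th1 cells	immune_cell_type	APBB2	APOD	ATP9A	BST2	BTG3	CCL4	CD38	CD70	CMAH	CSF2	CTLA4	DGKI	DOK5	DPP4	DUSP5	EGFL6	GGT1	HBEGF	IFNG	IL12RB2	IL22	LRP8	LTA	SGCB	STAT4	SYNGR3	TBX21	ZBTB32
Th17 cells	immune_cell_type	IL17A	IL17RA
Th2 cells	immune_cell_type	ADCY1	AHI1	ANK1	BIRC5	CCR4	CDC25C	CDC7	CENPF	CXCR6	DHFR	EVX1	GATA3	GSTA4	HELLS	IL13	IL26	LAIR2	LIMA1	MB	MICAL2	NEIL3	PHEX	PMCH	PTGIS	SLC39A14	SMAD2	SNRPD1	WDHD1
Treg	immune_cell_type	FOXP3
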