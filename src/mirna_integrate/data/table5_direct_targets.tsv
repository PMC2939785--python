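mirna_id	gene_symbol
miR-29a	MGC21874
miR-29a	BRWD1
miR-29a	MIER3
miR-29a	HBP1
miR-29a	THSD4
miR-29a	FAM116A
miR-29a	USP37
miR-29a	AFF4
miR-29a	ZBTB40
miR-29a	UBTF
miR-29a	SP1
miR-29a	PALM
miR-29a	DNAL1
miR-29a	MTX3
miR-29a	MAP2K4
miR-29a	KIAA0831
miR-29a	SLC39A9
miR-29a	JMJD2B
miR-29a	LCORL
miR-29a	KLHL9
miR-29a	SESTD1
miR-29a	RERE
miR-29a	C5orf24
miR-29a	USP34
miR-29a	NEBL
miR-29a	PIAS4
miR-29a	NKTR
miR-29a	JARID1A
miR-29a	AMFR
miR-29a	ARPP-19
miR-29a	CCNL2
miR-29a	CAPN7
miR-29a	BSDC1
miR-29a	TTC30B
miR-29a	ELF2
miR-29a	RAP1GDS1
miR-29a	LNPEP
miR-29a	GCC2
miR-29a	ERLIN2
miR-29a	PAN2
miR-29a	NCOR2
miR-29a	GNG12
miR-29a	EML5
miR-29a	STX17
miR-29a	CNOT8
miR-29a	MSL-1
miR-29a	RHBDD1
miR-29a	tcag7.1228
miR-29a	ATRN
miR-29a	FAM168B
miR-29a	PRPF40A
miR-29a	DICER1
miR-29a	KLHL28
miR-29a	PAIP2
miR-29a	BTBD7
miR-29a	ARFGEF2
miR-29a	LOC153364
miR-29a	SR140
miR-29a	BTG2
miR-29a	C19orf6
miR-29a	RIT1
miR-29a	SLC7A6
miR-29a	EML4
miR-29a	TTYH2
miR-29a	TNFAIP3
miR-29a	FBXL11
miR-29a	NANP
miR-29a	NUP160
miR-29a	TRAM2
miR-29a	NANOS1
miR-29a	IFI30
miR-29a	CDK6
miR-29a	MLXIP
miR-29a	MYCN
miR-29a	MAPRE2
miR-29a	MAP4K4
miR-29a	CHFR
miR-29a	LUZP1
miR-29a	SLC36A1
miR-29a	TRIB2
miR-29a	FSTL1
miR-29a	SLC16A14
miR-29a	CBX2
miR-29a	MEST
miR-29a	NCOA3
miR-29a	CDCA4
miR-29a	DIO2
miR-29a	DNAJB11
miR-29a	DNMT3A
miR-29a	NUFIP2
miR-29a	IMPDH1
miR-29a	INSIG1
miR-29a	OSBPL3
miR-29a	MAPRE1
miR-29a	PHACTR2
miR-29a	TFEC
miR-29a	EIF4E2
miR-29a	ABCE1
miR-29a	TSPAN14
miR-29a	SERPINH1
miR-29a	B3GNT5
miR-29a	PLXNA1
miR-29a	RPS6KA3
miR-29a	GNB4
miR-29a	DTX4
miR-29a	HMGCS1
miR-29a	DEF8
miR-29a	KIAA1128
miR-29a	COMMD2
miR-29a	SLC2A3
miR-29a	MYBL2
miR-29a	TET3
miR-29a	CCNJ
miR-29a	TMEM65
miR-29a	DPP4
miR-29a	JOSD1
miR-29a	DNMT3B
miR-29a	TAF11
miR-29a	CYCS
miR-29a	TBC1D7
miR-29a	CHIC2
miR-30b	NRIP1
miR-30b	RAPGEF6
miR-30b	BECN1
miR-30b	TRPS1
miR-30b	HIPK2
miR-30b	NF1
miR-30b	VAPA
miR-30b	BRWD1
miR-30b	SLC1A2
miR-30b	IGF1R
miR-30b	USP37
miR-30b	CSNK1G1
miR-30b	MIER3
miR-30b	TSGA14
miR-30b	KCTD3
miR-30b	KIAA1712
miR-30b	AFF3
miR-30b	ANKHD1
miR-30b	ZNF770
miR-30b	C2orf55
miR-30b	CHD1
miR-30b	SLC4A7
miR-30b	GIGYF2
miR-30b	CPEB4
miR-30b	IRS1
miR-30b	CCNT2
miR-30b	MKL2
miR-30b	CSAD
miR-30b	PAPOLA
miR-30b	VAV3
miR-30b	LCORL
miR-30b	C15orf29
miR-30b	DCTN4
miR-30b	SCAMP1
miR-30b	NEK4
miR-30b	MTX3
miR-30b	PHF13
miR-30b	ELOVL5
miR-30b	CCPG1
miR-30b	MAGI2
miR-30b	AFF4
miR-30b	LASS6
miR-30b	GZF1
miR-30b	CPEB2
miR-30b	FLJ40142
miR-30b	HNRNPA3
miR-30b	BCL2L11
miR-30b	ZBTB40
miR-30b	ABHD2
miR-30b	EPC2
miR-30b	ZNF148
miR-30b	SNX1
miR-30b	TNKS
miR-30b	ATRN
miR-30b	PHC3
miR-30b	TTC8
miR-30b	REV1
miR-30b	MNT
miR-30b	ARID4A
miR-30b	MGC21874
miR-30b	PPP1R9A
miR-30b	RBM12
miR-30b	FBXL17
miR-30b	ZDHHC17
miR-30b	KIAA1632
miR-30b	USP47
miR-30b	TMEM106B
miR-30b	PCGF3
miR-30b	KIAA0999
miR-30b	MSI2
miR-30b	CLCC1
miR-30b	MBD6
miR-30b	SIRT1
miR-30b	PSME3
miR-30b	PIP4K2B
miR-30b	CXorf39
miR-30b	KIF3A
miR-30b	TTC39A
miR-30b	IRS2
miR-30b	FAM110B
miR-30b	BCL6
miR-30b	PNKD
miR-30b	PAWR
miR-30b	PPAPDC1B
miR-30b	BCL2
miR-30b	MARCKS
miR-30b	SH2B3
miR-30b	ZNRF1
miR-30b	WDR26
miR-30b	CHFR
miR-30b	IGF2R
miR-30b	LYCAT
miR-30b	CAMK2D
miR-30b	ARL4C
miR-30b	CCNK
miR-30b	IFNAR2
miR-30b	NT5E
miR-30b	SLC36A1
miR-30b	FBXO45
miR-30b	MFHAS1
miR-30b	PHACTR2
miR-30b	TET3
miR-30b	EML4
miR-30b	SMAP1
miR-30b	FAM152A
miR-30b	CALU
miR-30b	TRAM2
miR-30b	ITGA5
miR-30b	KPNA3
miR-30b	GRK6
miR-30b	LYN
miR-30b	SURF4
miR-30b	RASSF4
miR-30b	RAP2B
miR-30b	NRBF2
miR-30b	NCOA3
miR-30b	FAM43A
miR-30b	LMBR1L
miR-30b	MAP4K4
miR-30b	SUV39H2
miR-30b	MYO5A
miR-30b	KLHL20
miR-30b	ME1
miR-30b	DNMT3A
miR-30b	MYBL2
miR-30b	LCP1
miR-30b	SMAD1
miR-30b	KIAA1949
miR-30b	PHTF2
miR-30b	SPTLC2
miR-30b	CHST2
miR-30b	QKI
miR-30b	SOCS1
miR-30b	SEC24A
miR-30b	FLJ36031
miR-30b	CLN8
miR-30b	CAPZA1
miR-30b	DBF4
miR-30b	KLF11
miR-30b	IDH1
miR-342-3p	MRFAP1
miR-342-3p	CA12
miR-342-3p	ACVR2B
miR-342-3p	PCGF3
miR-342-3p	MSI2
miR-342-3p	LARP4
miR-342-3p	ZAK
miR-342-3p	AAMP
miR-342-3p	HIP1
miR-342-3p	NBEA
miR-342-3p	UQCC
miR-342-3p	PTRF
miR-342-3p	SHE
miR-342-3p	ID4
miR-342-3p	SSR1
miR-342-3p	MEX3A
miR-342-3p	PDGFRA
miR-342-3p	NCOA7
miR-342-3p	CDK6
miR-520a-5p	PPP1R9B
miR-520a-5p	SMEK1
miR-520a-5p	HEG1
miR-520a-5p	SLC25A13
miR-520a-5p	TMPO
miR-520a-5p	ABCE1
miR-520a-5p	KPNA1
miR-520a-5p	PTP4A2
miR-520a-5p	BAG1
miR-520a-5p	ARHGEF12
miR-520a-5p	NOVA1
miR-520a-5p	PDPK1
miR-520a-5p	LZTFL1
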