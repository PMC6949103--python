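pathway	protein	sign
Apoptosis	BAK	1
Apoptosis	BAX	1
Apoptosis	BID	1
Apoptosis	BIM	1
Apoptosis	CASPASE7CLEAVED	1
Apoptosis	BCL2	-1
Apoptosis	BCLXL	-1
Apoptosis	CIAP	-1
Cell Cycle	CDK1	1
Cell Cycle	CYCLINB1	1
Cell Cycle	CYCLINE1	1
Cell Cycle	CYCLINE2	1
Cell Cycle	FOXM1	1
Cell Cycle	PCNA	1
Cell Cycle	P27_pT157	1
Cell Cycle	P27_pT198	1
DNA Damage Response	X53BP1	1
DNA Damage Response	ATM	1
DNA Damage Response	BRCA2	1
DNA Damage Response	CHK1_pS345	1
DNA Damage Response	CHK2_pT68	1
DNA Damage Response	KU80	1
DNA Damage Response	MRE11	1
DNA Damage Response	P53	1
DNA Damage Response	RAD50	1
DNA Damage Response	RAD51	1
DNA Damage Response	XRCC1	1
EMT	COLLAGENVI	1
EMT	FIBRONECTIN	1
EMT	HEREGULIN	1
EMT	NCADHERIN	1
EMT	PAI1	1
EMT	CLAUDIN7	-1
EMT	ECADHERIN	-1
EMT	BETACATENIN	-1
EMT	RBM15	-1
Hormone AR	AR	1
Hormone AR	BCL2_AR	1
Hormone AR	INPP4B_AR	1
Hormone AR	GATA3	1
Hormone ER	ERALPHA	1
Hormone ER	ERALPHA_pS118	1
Hormone ER	PR	1
PI3K/AKT	AKT_pS473	1
PI3K/AKT	AKT_pT308	1
PI3K/AKT	GSK3_pS9	1
PI3K/AKT	GSK3AB_pS21S9	1
PI3K/AKT	PRAS40_pT246	1
PI3K/AKT	TUBERIN_pT1462	1
PI3K/AKT	INPP4B	-1
PI3K/AKT	PTEN	-1
RAS/MAPK	ARAF_pS299	1
RAS/MAPK	CJUN_pS73	1
RAS/MAPK	CRAF_pS338	1
RAS/MAPK	JNK_pT183Y185	1
RAS/MAPK	MAPK_pT202Y204	1
RAS/MAPK	MEK1_pS217S221	1
RAS/MAPK	P38_pT180Y182	1
RAS/MAPK	P90RSK_pT359S363	1
RAS/MAPK	YB1_pS102	1
RTK	EGFR_pY1068	1
RTK	EGFR_pY1173	1
RTK	HER2_pY1248	1
RTK	HER3_pY1289	1
RTK	SHC_pY317	1
RTK	SRC_pY416	1
RTK	SRC_pY527	-1
TSC/mTOR	X4EBP1_pS65	1
TSC/mTOR	X4EBP1_pT37T46	1
TSC/mTOR	X4EBP1_pT70	1
TSC/mTOR	MTOR_pS2448	1
TSC/mTOR	P70S6K_pT389	1
TSC/mTOR	RICTOR_pT1135	1
TSC/mTOR	S6_pS235S236	1
TSC/mTOR	S6_pS240S244	1
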