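AGE-RAGE signaling pathway in diabetic complications	KEGG pathway	AGT	BCL2	CXCL8	IL1A	IL1B	IL6	MAPK14	MAPK8	NFKB1	NOX1	SERPINE1	SMAD2	TGFB1	TNF
Ovarian steroidogenesis	KEGG pathway	AKR1C3	BMP15	CYP17A1	CYP19A1	FSHB	IGF1	INS	INSR	LDLR	LHCGR
FoxO signaling pathway	KEGG pathway	ATM	BCL2L11	EP300	IGF1	G6PC	IL6	INS	INSR	IRS1	IRS2	MAPK14	MAPK8	PTEN	SOD2	TGFB1
Non-alcoholic fatty liver disease	KEGG pathway	BCL2L11	CXCL8	GPT	GOT1	IL1A	IL1B	IL6	INS	INSR	IRS1	IRS2	MAPK8	NFKB1	TGFB1	TNF
Ferroptosis	KEGG pathway	ACSL4	FTL	GPX4	PCBP1	PCBP2	SLC11A2	SLC7A11	TFRC	TP53
Pathways in cancer	KEGG pathway	AGT	AR	BCL2	BCL2L11	CXCL8	EP300	ESR1	ESR2	FGFR2	GSTA1	GSTA2	HIF1A	IGF1	IGF2	IL6	ITGB1	MAPK8	NFE2L2	NFKB1	PPARG	PTEN	SMAD2	TCF7L2	TGFB1	TP53	ZBTB16
Cellular senescence	KEGG pathway	ATM	CAPN1	CXCL8	GATA4	IL1A	IL6	MAPK14	NFKB1	PTEN	RAD50	SERPINE1	SMAD2	TGFB1	TP53
TGF-beta signaling pathway	KEGG pathway	AMH	AMHR2	BMPR1B	DCN	EP300	HAMP	SMAD2	TGFB1	TNF
Insulin resistance	KEGG pathway	AGT	CREB1	G6PC	IL6	INS	INSR	IRS1	IRS2	MAPK8	NFKB1	PTEN	PTPN11	TNF
Prolactin signaling pathway	KEGG pathway	CYP17A1	ESR1	ESR2	INS	IRF1	LHCGR	MAPK14	MAPK8	NFKB1	HIF1A
Type II diabetes mellitus	KEGG pathway	INS	INSR	IRS1	IRS2	MAPK8	TNF
Endocrine resistance	KEGG pathway	BCL2	ESR1	ESR2	IGF1	MAPK14	MAPK8	NCOR1	TP53
Apoptosis	KEGG pathway	ACTB	ATM	BCL2	BCL2L11	CAPN1	MAPK8	NFKB1	TNF	TP53
Neuroactive ligand-receptor interaction	KEGG pathway	AGT	AVP	CCK	CNR1	FSHB	GCG	GHSR	GLP1R	GLP2R	GNRH1	GNRHR	KISS1	KISS1R	LHCGR
Aldosterone-regulated sodium reabsorption	KEGG pathway	IGF1	INS	INSR	IRS1	NEDD4L
GnRH secretion	KEGG pathway	ESR2	GNRH1	KISS1	KISS1R
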