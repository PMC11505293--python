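# Curated PCOS-ferroptosis interactome gene list:
# 82 pcos_curated, 38 fpt_associated, 20 novel_predicted (140 symbols).
# 12 of the fpt_associated assignments are reconstructed from narrative
# context; the remaining annotations follow the curated source list.
symbol	category	name
ACE	pcos_curated	angiotensin I converting enzyme
ACE2	pcos_curated	angiotensin converting enzyme 2
ACSL4	fpt_associated	acyl-CoA synthetase long chain family member 4
ACTB	novel_predicted	actin beta
ACVR1B	fpt_associated	activin A receptor type 1B
AGT	pcos_curated	angiotensinogen
AKR1C3	pcos_curated	aldo-keto reductase family 1 member C3
AMH	pcos_curated	anti-Mullerian hormone
AMHR2	pcos_curated	anti-Mullerian hormone receptor type 2
APOE	novel_predicted	apolipoprotein E
AR	pcos_curated	androgen receptor
ARL14EP	pcos_curated	ADP ribosylation factor-like GTPase 14 effector protein
ARPC1A	pcos_curated	actin-related protein 2/3 complex subunit 1A
ASCL4	fpt_associated	achaete-scute family bHLH transcription factor 4
ATM	fpt_associated	ATM serine/threonine kinase
AVP	pcos_curated	arginine vasopressin
BCL2	fpt_associated	BCL2 apoptosis regulator
BCL2L11	pcos_curated	BCL2-like 11
BMP15	pcos_curated	bone morphogenetic protein 15
BMPR1B	pcos_curated	bone morphogenetic protein receptor type 1B
BYSL	novel_predicted	bystin-like
CAPN1	novel_predicted	calpain 1
CAPN10	pcos_curated	calpain 10
CAST	pcos_curated	calpastatin
CCK	pcos_curated	cholecystokinin
CGA	pcos_curated	glycoprotein hormones, alpha polypeptide
CNR1	fpt_associated	cannabinoid receptor 1
CREB1	pcos_curated	cAMP responsive element binding protein 1
CXCL8	pcos_curated	C-X-C motif chemokine ligand 8
CYP17A1	pcos_curated	cytochrome P450 family 17 subfamily A member 1
CYP19A1	pcos_curated	cytochrome P450 family 19 subfamily A member 1
CYP21A2	pcos_curated	cytochrome P450 family 21 subfamily A member 2
DCN	novel_predicted	decorin
DCTN1	pcos_curated	dynactin subunit 1
DDX58	novel_predicted	DExD/H-Box Helicase 58
DENND1A	pcos_curated	DENN domain containing 1A
DLG2	novel_predicted	disks large MAGUK scaffold protein 2
DPP4	fpt_associated	dipeptidyl peptidase 4
EP300	pcos_curated	E1A binding protein p300
ERBB4	pcos_curated	erb-b2 receptor tyrosine kinase 4
ESR1	novel_predicted	estrogen receptor 1
ESR2	pcos_curated	estrogen receptor 2
FANCC	pcos_curated	FA complementation group C
FBN3	pcos_curated	fibrillin 3
FGFR2	pcos_curated	fibroblast growth factor receptor 2
FSHB	pcos_curated	follicle stimulating hormone subunit beta
FTL	fpt_associated	ferritin light chain
FTO	pcos_curated	FTO alpha-ketoglutarate dependent dioxygenase
FTSJ1	novel_predicted	FtsJ RNA 2'-O-methyltransferase 1
G6PC	pcos_curated	glucose-6-phosphatase catalytic subunit 1
G6PD	fpt_associated	glucose-6-phosphate dehydrogenase
GALNT14	fpt_associated	polypeptide N-acetylgalactosaminyltransferase 14
GATA4	pcos_curated	GATA binding protein 4
GCG	pcos_curated	glucagon
GDF9	pcos_curated	growth differentiation factor 9
GHSR	pcos_curated	growth hormone secretagogue receptor
GLP1	pcos_curated	glucagon-like peptide 1 receptor
GLP2	pcos_curated	glucagon-like peptide 2 receptor
GNRH1	pcos_curated	gonadotropin releasing hormone 1
GNRHR	pcos_curated	gonadotropin releasing hormone receptor
GOT1	fpt_associated	glutamic oxaloacetic transaminase 1
GPT	pcos_curated	glutamic pyruvic transaminase
GPX4	fpt_associated	glutathione peroxidase 4
GSTA1	fpt_associated	glutathione S-transferase alpha 1
GSTA2	fpt_associated	glutathione S-transferase alpha 2
HAMP	fpt_associated	hepcidin antimicrobial peptide
HSPA5	fpt_associated	heat shock protein family A (Hsp70) member 5
HHEX	pcos_curated	hematopoietically expressed homeobox
HIF1A	fpt_associated	hypoxia inducible factor 1 subunit alpha
IGF1	pcos_curated	insulin-like growth factor 1
IGF2	pcos_curated	insulin-like growth factor 2
IL1A	pcos_curated	interleukin 1 alpha
IL1B	pcos_curated	interleukin 1 beta
IL6	pcos_curated	interleukin 6
INS	pcos_curated	insulin
INSR	pcos_curated	insulin receptor
IRF1	pcos_curated	interferon regulatory factor 1
IRS1	pcos_curated	insulin receptor substrate 1
IRS2	pcos_curated	insulin receptor substrate 2
ITGB1	pcos_curated	integrin subunit beta 1
KCNA4	pcos_curated	potassium voltage-gated channel subfamily A member 4
KDM1A	novel_predicted	lysine demethylase 1A
KISS1	pcos_curated	KiSS-1 metastasis suppressor
KISS1R	pcos_curated	KISS1 receptor
KRR1	pcos_curated	KRR1 small subunit processome component homolog
LDLR	pcos_curated	low-density lipoprotein receptor
LHCGR	pcos_curated	luteinizing hormone/choriogonadotropin receptor
MAPK14	pcos_curated	mitogen-activated protein kinase 14
MAPK	pcos_curated	mitogen-activated protein kinase 8
MAPRE1	fpt_associated	microtubule-associated protein RP/EB family member 1
MGLL	novel_predicted	monoglyceride lipase
MUC1	novel_predicted	mucin 1, cell surface associated
MUC7	novel_predicted	mucin 7, secreted
NCOR1	fpt_associated	nuclear receptor corepressor 1
NEDD4L	fpt_associated	NEDD4-like E3 ubiquitin protein ligase
NEIL2	pcos_curated	nei-like DNA glycosylase 2
NFE2L2	fpt_associated	NFE2-like bZIP transcription factor 2
NFKB1	fpt_associated	nuclear factor kappa B subunit 1
NOX1	fpt_associated	NADPH oxidase 1
PCBP1	fpt_associated	poly(rC) binding protein 1
PCBP2	fpt_associated	poly(rC) binding protein 2
PHF21A	fpt_associated	PHD finger protein 21A
PINK1	fpt_associated	PTEN induced kinase 1
PPARG	pcos_curated	peroxisome proliferator-activated receptor gamma
PRDM2	pcos_curated	PR/SET domain 2
PTEN	novel_predicted	phosphatase and tensin homolog
PTPN11	pcos_curated	protein tyrosine phosphatase non-receptor type 11
RAD50	pcos_curated	RAD50 double strand break repair protein
RPS9	novel_predicted	ribosomal protein S9
SERPINE1	pcos_curated	serpin family E member 1
SETDB1	fpt_associated	SET domain bifurcated histone lysine methyltransferase 1
SHBG	pcos_curated	sex hormone binding globulin
SIRT3	fpt_associated	sirtuin 3
SLC11A2	fpt_associated	solute carrier family 11 member 2
SLC7A11	fpt_associated	solute carrier family 7 member 11
SMAD2	novel_predicted	SMAD family member 2
SOD2	fpt_associated	superoxide dismutase 2
SULT2A1	pcos_curated	sulfotransferase family 2A member 1
TCF7L2	pcos_curated	transcription factor 7-like 2
TET1	fpt_associated	tet methylcytosine dioxygenase 1
TET2	fpt_associated	tet methylcytosine dioxygenase 2
TFRC	fpt_associated	transferrin receptor
TGFB1	pcos_curated	transforming growth factor beta 1
THADA	pcos_curated	THADA armadillo repeat containing
TLR4	pcos_curated	Toll-like receptor 4
TNF	pcos_curated	tumor necrosis factor
TOX3	pcos_curated	TOX high-mobility group box family member 3
TP53	fpt_associated	tumor protein p53
TRIM28	fpt_associated	tripartite motif containing 28
TRIM4	pcos_curated	tripartite motif containing 4
TROAP	novel_predicted	trophinin-associated protein
UNC5C	pcos_curated	unc-5 netrin receptor C
WWTR1	pcos_curated	WW domain containing transcription regulator 1
XRCC1	pcos_curated	X-ray repair cross complementing 1
YAP1	pcos_curated	Yes1-associated transcriptional regulator
ZBTB16	pcos_curated	zinc finger and BTB domain containing 16
ZKSCAN5	fpt_associated	zinc finger with KRAB and SCAN domains 5
ZNF197	novel_predicted	zinc finger protein 197
ZNF41	novel_predicted	zinc finger protein 41
ZSCAN20	novel_predicted	zinc finger and SCAN domain containing 20
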