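# Synthetic central-carbon-metabolism network for a PTS-minus, shikimate-
# overproducing E. coli strain grown on glucose (GLC) + yeast extract (YE).
# This file is a SYNTHETIC reconstruction assembled from the pathway
# narrative of the study system (EMP glycolysis, oxidative/non-oxidative PPP,
# Entner-Doudoroff, TCA, glyoxylate shunt, anaplerosis, acetate metabolism,
# respiration/maintenance, YE decomposition, shikimate biosynthesis), sized
# to exactly 60 reactions, 44 internal metabolites and 6 external species.
# Lumped steps are commented on their reaction line.  The network is carbon
# balanced (cofactor moieties carry no carbon; the MAINT sink collects both
# maintenance ATP turnover and vented CO2).
#
# ---- external species -------------------------------------------------
@metabolite	GLC	glucose	1
@metabolite	YE	yeast extract	1
@metabolite	SA	shikimic acid	1
@metabolite	AC	acetate (extracellular)	1
@metabolite	BIOMASS	biomass	1
@metabolite	MAINT	maintenance / vented-CO2 sink	1
# ---- internal metabolites: glycolysis ---------------------------------
@metabolite	G6P	glucose-6-phosphate	0
@metabolite	F6P	fructose-6-phosphate	0
@metabolite	FDP	fructose-1,6-bisphosphate	0
@metabolite	GAP	glyceraldehyde-3-phosphate	0
@metabolite	PG3	3-phosphoglycerate	0
@metabolite	PEP	phosphoenolpyruvate	0
@metabolite	PYR	pyruvate	0
# ---- pentose phosphate / Entner-Doudoroff -----------------------------
@metabolite	PGL	6-phosphogluconolactone	0
@metabolite	PGC	6-phosphogluconate	0
@metabolite	RU5P	ribulose-5-phosphate	0
@metabolite	X5P	xylulose-5-phosphate	0
@metabolite	R5P	ribose-5-phosphate	0
@metabolite	S7P	sedoheptulose-7-phosphate	0
@metabolite	E4P	erythrose-4-phosphate	0
@metabolite	KDPG	2-keto-3-deoxy-6-phosphogluconate	0
# ---- acetate metabolism -----------------------------------------------
@metabolite	ACCOA	acetyl-CoA	0
@metabolite	ACTP	acetyl phosphate	0
@metabolite	ACIN	acetate (intracellular)	0
# ---- TCA cycle and glyoxylate shunt -----------------------------------
@metabolite	OAA	oxaloacetate	0
@metabolite	CIT	citrate	0
@metabolite	ICIT	isocitrate	0
@metabolite	AKG	2-ketoglutarate	0
@metabolite	SUCCOA	succinyl-CoA	0
@metabolite	SUC	succinate	0
@metabolite	FUM	fumarate	0
@metabolite	MAL	malate	0
@metabolite	GLX	glyoxylate	0
@metabolite	CO2	carbon dioxide	0
# ---- shikimate biosynthesis -------------------------------------------
@metabolite	DAHP	3-deoxy-D-arabino-heptulosonate-7-phosphate	0
@metabolite	DHQ	3-dehydroquinate	0
@metabolite	DHS	3-dehydroshikimate	0
@metabolite	SHIK	shikimate (intracellular)	0
# ---- yeast-extract derived pools --------------------------------------
@metabolite	BIOMp	biomass precursor pool	0
@metabolite	AAA	aromatic amino acids (lumped)	0
@metabolite	ALA	alanine	0
@metabolite	GLU	glutamate	0
# ---- cofactors --------------------------------------------------------
@metabolite	ATP	ATP	0
@metabolite	ADP	ADP	0
@metabolite	NAD	NAD+	0
@metabolite	NADH	NADH	0
@metabolite	NADP	NADP+	0
@metabolite	NADPH	NADPH	0
@metabolite	Q	ubiquinone (oxidized)	0
@metabolite	QH2	ubiquinol	0
# ---- reactions: glucose uptake and EMP glycolysis ---------------------
# galactose-permease transport lumped with glucokinase phosphorylation
GalP	0	GLC + ATP -> G6P + ADP
Pgi	1	G6P <-> F6P
Pfk	0	F6P + ATP -> FDP + ADP
# Fba lumped with triose-phosphate isomerase (TpiA)
Fba	0	FDP -> 2 GAP
# GapA lumped with phosphoglycerate kinase (Pgk)
GapA	0	GAP + NAD + ADP -> PG3 + NADH + ATP
# phosphoglycerate mutase + enolase lumped
Eno	0	PG3 -> PEP
PykA	0	PEP + ADP -> PYR + ATP
PpsA	0	PYR + 2 ATP -> PEP + 2 ADP
# ---- pentose phosphate pathway ----------------------------------------
G6Pdh	0	G6P + NADP -> PGL + NADPH
Pgl	0	PGL -> PGC
Gnd	0	PGC + NADP -> RU5P + CO2 + NADPH
Rpe	1	RU5P <-> X5P
Rpi	1	RU5P <-> R5P
TktA1	0	R5P + X5P -> S7P + GAP
Tal	0	S7P + GAP -> E4P + F6P
# transketolase II half-reaction oriented toward net E4P formation
TktA2	0	F6P + GAP -> X5P + E4P
# ---- Entner-Doudoroff pathway -----------------------------------------
PGdh	0	PGC -> KDPG
KDPGa	0	KDPG -> GAP + PYR
# ---- pyruvate and acetate metabolism ----------------------------------
LpdA	0	PYR + NAD -> ACCOA + CO2 + NADH
PoxB	0	PYR + Q -> ACIN + CO2 + QH2
Pta	1	ACCOA <-> ACTP
AckA	1	ACTP + ADP <-> ACIN + ATP
# Acs lumps the AMP-forming step as a 2-ATP cost
Acs	0	ACIN + 2 ATP -> ACCOA + 2 ADP
ActPout	0	ACIN -> AC
ActPin	0	AC -> ACIN
# ---- TCA cycle --------------------------------------------------------
Csyn	0	ACCOA + OAA -> CIT
Acn	1	CIT <-> ICIT
IcdA	1	ICIT + NADP <-> AKG + CO2 + NADPH
KGdh	0	AKG + NAD -> SUCCOA + CO2 + NADH
SucCD	0	SUCCOA + ADP -> SUC + ATP
SdhABCD	0	SUC + Q -> FUM + QH2
Fum	1	FUM <-> MAL
Mdh	1	MAL + NAD <-> OAA + NADH
# fumarate reductase: completes a futile quinone cycle with SdhABCD
Frd	0	FUM + QH2 -> SUC + Q
# ---- glyoxylate shunt -------------------------------------------------
Icl	0	ICIT -> GLX + SUC
Msn	0	GLX + ACCOA -> MAL
# ---- anaplerotic reactions --------------------------------------------
Ppc	0	PEP + CO2 -> OAA
PckA	0	OAA + ATP -> PEP + CO2 + ADP
MaeA	0	MAL + NAD -> PYR + CO2 + NADH
MaeB	0	MAL + NADP -> PYR + CO2 + NADPH
# ---- shikimate biosynthesis (aroK/aroL absent: SHIK is terminal) ------
DAHPs	0	PEP + E4P -> DAHP
DHQs	0	DAHP -> DHQ
DHQd	0	DHQ -> DHS
SDH	0	DHS + NADPH -> SHIK + NADP
SAout	0	SHIK -> SA
# ---- yeast-extract decomposition (coefficients are fixture constants,
# chosen carbon-consistent across the three routes) ----------------------
YEup1	0	YE -> 0.6 BIOMp + 0.42 AAA
YEup2	0	YE -> 0.75 ALA + 0.75 GLU
YEup3	0	YE -> 0.4 BIOMp + 0.2 AAA + 0.34 ALA + 0.34 GLU
DadA	0	ALA + NAD -> PYR + NADH
Gdh	0	GLU + NAD -> AKG + NADH
GltBD	0	AKG + NADPH -> GLU + NADP
AlaA	0	PYR + GLU -> ALA + AKG
# ---- biomass formation (lumped precursor demand) ----------------------
BIOMpSyn	0	0.5 PYR + 0.3 OAA + 0.2 AKG + 2 ATP -> BIOMp + 2 ADP
BIOMsyn	0	0.7 BIOMp + 0.3 AAA + 2 ATP -> BIOMASS + 2 ADP
# ---- respiration, energy and maintenance ------------------------------
NADHdh	0	NADH + Q -> NAD + QH2
Cyo	0	QH2 + 2 ADP -> Q + 2 ATP
ATPm	0	ATP -> ADP + MAINT
CO2out	0	CO2 -> MAINT
Pnt	0	NADH + NADP -> NAD + NADPH
SthA	0	NADPH + NAD -> NADP + NADH
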