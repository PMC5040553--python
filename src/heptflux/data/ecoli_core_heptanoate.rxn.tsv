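id	equation	lb	ub	subsystem
EX_glc	glc <=> glc_e	-10	0	Exchange
EX_o2	o2 <=> o2_e	-1000	0	Exchange
EX_co2	co2 <=> co2_e	-1000	1000	Exchange
EX_ac	ac -> ac_e	0	1000	Exchange
EX_lac	lac -> lac_e	0	1000	Exchange
EX_etoh	etoh -> etoh_e	0	1000	Exchange
EX_nh4	nh4 <=> nh4_e	-1000	0	Exchange
EX_h2o	h2o <=> h2o_e	-1000	1000	Exchange
EX_biomass	biomass -> biomass_e	0	1000	Exchange
GLK	atp + glc -> adp + g6p	0	1000	Glycolysis
PTS	glc + pep -> g6p + pyr	0	1000	Glycolysis
PGI	g6p <=> f6p	-1000	1000	Glycolysis
PFK	atp + f6p -> adp + fdp	0	1000	Glycolysis
FBP	fdp + h2o -> f6p + pi	0	1000	Gluconeogenesis
FBA	fdp <=> dhap + g3p	-1000	1000	Glycolysis
TPI	dhap <=> g3p	-1000	1000	Glycolysis
GAPD	g3p + nad + pi <=> 13dpg + nadh	-1000	1000	Glycolysis
PGK	13dpg + adp <=> atp + pg3	-1000	1000	Glycolysis
PGM	pg3 <=> pg2	-1000	1000	Glycolysis
ENO	pg2 <=> h2o + pep	-1000	1000	Glycolysis
PYK	adp + pep -> atp + pyr	0	1000	Glycolysis
PDH	coa + nad + pyr -> accoa + co2 + nadh	0	1000	Glycolysis
G6PDH	g6p + nadp -> 6pg + nadph	0	1000	PentosePhosphate
GND	6pg + nadp -> co2 + nadph + ru5p	0	1000	PentosePhosphate
RPE	ru5p <=> x5p	-1000	1000	PentosePhosphate
RPI	ru5p <=> r5p	-1000	1000	PentosePhosphate
TKT1	r5p + x5p <=> g3p + s7p	-1000	1000	PentosePhosphate
TAL	g3p + s7p <=> e4p + f6p	-1000	1000	PentosePhosphate
TKT2	e4p + x5p <=> f6p + g3p	-1000	1000	PentosePhosphate
CS	accoa + h2o + oaa -> cit + coa	0	1000	TCA
ACONT	cit <=> icit	-1000	1000	TCA
ICD	icit + nadp <=> akg + co2 + nadph	-1000	1000	TCA
AKGDH	akg + coa + nad -> co2 + nadh + succoa	0	1000	TCA
SUCOAS	adp + pi + succoa <=> atp + coa + succ	-1000	1000	TCA
SUCDH	fad + succ -> fadh2 + fum	0	1000	TCA
FRD	fadh2 + fum -> fad + succ	0	1000	TCA
FUM	fum + h2o <=> mal	-1000	1000	TCA
MDH	mal + nad <=> nadh + oaa	-1000	1000	TCA
ICL	icit -> glx + succ	0	1000	Glyoxylate
MALS	accoa + glx + h2o -> coa + mal	0	1000	Glyoxylate
PPC	co2 + h2o + pep -> oaa + pi	0	1000	Anaplerosis
PCK	atp + oaa -> adp + co2 + pep	0	1000	Anaplerosis
ME1	mal + nadp -> co2 + nadph + pyr	0	1000	Anaplerosis
ME2	mal + nad -> co2 + nadh + pyr	0	1000	Anaplerosis
PTA	accoa + pi <=> actp + coa	-1000	1000	Fermentation
ACK	actp + adp <=> ac + atp	-1000	1000	Fermentation
POX	0.5 o2 + pyr -> ac + co2	0	1000	Fermentation
ACALD	accoa + nadh <=> acald + coa + nad	-1000	1000	Fermentation
ALCD	acald + nadh <=> etoh + nad	-1000	1000	Fermentation
LDH	nadh + pyr <=> lac + nad	-1000	1000	Fermentation
GDH	akg + nadph + nh4 -> glu + h2o + nadp	0	1000	Nitrogen
NDH1	2 adp + nadh + 0.5 o2 + 2 pi -> 2 atp + 3 h2o + nad	0	1000	OxidativePhosphorylation
NDH2	nadh + 0.5 o2 -> h2o + nad	0	1000	OxidativePhosphorylation
FADETC	adp + fadh2 + 0.5 o2 + pi -> atp + fad + 2 h2o	0	1000	OxidativePhosphorylation
THD_PNT	nadh + nadp -> nad + nadph	0	1000	Transhydrogenase
THD_UDH	nad + nadph -> nadh + nadp	0	1000	Transhydrogenase
ATPM	atp + h2o -> adp + pi	0	1000	Maintenance
BIOMASS	3.7478 accoa + 45 atp + 0.361 e4p + 0.0709 f6p + 0.129 g3p + 0.205 g6p + 4.9414 glu + 13.0279 nadph + 1.7867 oaa + 0.5191 pep + 1.496 pg3 + 2.8328 pyr + 0.8977 r5p -> 45 adp + 4.1182 akg + biomass + 3.7478 coa + 13.0279 nadp + 48.6787 pi	0	1000	Biomass
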