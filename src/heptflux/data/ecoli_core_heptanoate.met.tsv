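id	name	external	cofactor_role
glc_e	D-glucose (extracellular)	1	none
o2_e	oxygen (extracellular)	1	none
co2_e	carbon dioxide (extracellular)	1	none
ac_e	acetate (extracellular)	1	none
lac_e	D-lactate (extracellular)	1	none
etoh_e	ethanol (extracellular)	1	none
nh4_e	ammonium (extracellular)	1	none
h2o_e	water (extracellular)	1	none
biomass_e	biomass (extracellular)	1	none
glc	D-glucose	0	none
g6p	glucose 6-phosphate	0	none
f6p	fructose 6-phosphate	0	none
fdp	fructose 1,6-bisphosphate	0	none
dhap	dihydroxyacetone phosphate	0	none
g3p	glyceraldehyde 3-phosphate	0	none
13dpg	1,3-bisphosphoglycerate	0	none
pg3	3-phosphoglycerate	0	none
pg2	2-phosphoglycerate	0	none
pep	phosphoenolpyruvate	0	none
pyr	pyruvate	0	none
accoa	acetyl-CoA	0	none
coa	coenzyme A	0	none
actp	acetyl phosphate	0	none
ac	acetate	0	none
acald	acetaldehyde	0	none
etoh	ethanol	0	none
lac	D-lactate	0	none
6pg	6-phosphogluconate	0	none
ru5p	ribulose 5-phosphate	0	none
x5p	xylulose 5-phosphate	0	none
r5p	ribose 5-phosphate	0	none
s7p	sedoheptulose 7-phosphate	0	none
e4p	erythrose 4-phosphate	0	none
cit	citrate	0	none
icit	isocitrate	0	none
akg	2-oxoglutarate	0	none
succoa	succinyl-CoA	0	none
succ	succinate	0	none
fum	fumarate	0	none
mal	L-malate	0	none
oaa	oxaloacetate	0	none
glx	glyoxylate	0	none
glu	L-glutamate	0	none
nh4	ammonium	0	none
atp	ATP	0	ATP
adp	ADP	0	ADP
nad	NAD+	0	NAD
nadh	NADH	0	NADH
nadp	NADP+	0	NADP
nadph	NADPH	0	NADPH
fad	FAD	0	FAD
fadh2	FADH2	0	FADH2
pi	orthophosphate	0	Pi
co2	carbon dioxide	0	none
o2	oxygen	0	none
h2o	water	0	none
biomass	biomass	0	none
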