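# model_id=purine_core
# objective=BIOMASS
# objective_sense=max
reaction_id	equation	lower_bound	upper_bound	gpr	subsystem
BIOMASS	0.1 e4p + 1 pyr + 0.5 r5p <=> 1 biomass	0.0	1.0		biomass
DM_imp	1 imp <=>	0.0	1000.0		purine
EMP_LO	1 g3p <=> 1 pyr	0.0	1000.0		EMP
EX_biomass	1 biomass <=>	0.0	1000.0		exchange
EX_co2	1 co2 <=>	0.0	1000.0		exchange
EX_glc	1 glc_e <=>	-10.0	1000.0		exchange
EX_hyp	1 hyp <=>	0.0	1000.0		exchange
EX_ins	1 ins <=>	0.0	1000.0		exchange
EX_pyr	1 pyr <=>	0.0	1000.0		exchange
FBA	1 f6p <=> 2 g3p	0.0	1000.0	fbaA	EMP
GLK	1 glc_e <=> 1 g6p	0.0	1000.0	glcK	EMP
NUC	1 imp <=> 1 ins	0.0	1000.0		purine
PGI	1 g6p <=> 1 f6p	-1000.0	1000.0	pgi	EMP
PNP	1 ins <=> 1 hyp + 1 r1p	0.0	1000.0	deoD or pupG	purine
PPM	1 r1p <=> 1 r5p	0.5	1000.0	drm	purine
PRS	1 r5p <=> 1 prpp	0.0	1000.0	prs	purine
PUR	1 g3p + 1 prpp <=> 1 imp	0.0	1000.0	purOp	purine
RPE	1 ru5p <=> 1 x5p	-1000.0	1000.0		PPP
RPI	1 ru5p <=> 1 r5p	-1000.0	1000.0		PPP
TAL	1 g3p + 1 s7p <=> 1 e4p + 1 f6p	0.3	1000.0	ywjH	PPP
TKT1	1 r5p + 1 x5p <=> 1 g3p + 1 s7p	0.0	1000.0	tkt	PPP
TKT2	1 e4p + 1 x5p <=> 1 f6p + 1 g3p	-1000.0	1000.0	tkt	PPP
ZWF	1 g6p <=> 1 co2 + 1 ru5p	0.0	1000.0	zwf and ykgB	PPP
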