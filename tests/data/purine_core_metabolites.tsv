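metabolite_id	name	compartment	formula	charge
biomass	biomass	c		
co2	carbon dioxide	c		
e4p	erythrose 4-phosphate	c		
f6p	fructose 6-phosphate	c		
g3p	glyceraldehyde 3-phosphate	c		
g6p	glucose 6-phosphate	c		
glc_e	glucose (extracellular)	e		
hyp	hypoxanthine	c		
imp	inosine monophosphate	c		
ins	inosine	c		
prpp	phosphoribosyl pyrophosphate	c		
pyr	pyruvate	c		
r1p	ribose 1-phosphate	c		
r5p	ribose 5-phosphate	c		
ru5p	ribulose 5-phosphate	c		
s7p	sedoheptulose 7-phosphate	c		
x5p	xylulose 5-phosphate	c		
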