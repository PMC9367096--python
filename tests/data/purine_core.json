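{
 "genes": [
  "deoD",
  "drm",
  "fbaA",
  "glcK",
  "pgi",
  "prs",
  "pupG",
  "purOp",
  "tkt",
  "ykgB",
  "ywjH",
  "zwf"
 ],
 "id": "purine_core",
 "metabolites": [
  {
   "charge": null,
   "compartment": "c",
   "formula": null,
   "id": "biomass",
   "name": "biomass"
  },
  {
   "charge": null,
   "compartment": "c",
   "formula": null,
   "id": "co2",
   "name": "carbon dioxide"
  },
  {
   "charge": null,
   "compartment": "c",
   "formula": null,
   "id": "e4p",
   "name": "erythrose 4-phosphate"
  },
  {
   "charge": null,
   "compartment": "c",
   "formula": null,
   "id": "f6p",
   "name": "fructose 6-phosphate"
  },
  {
   "charge": null,
   "compartment": "c",
   "formula": null,
   "id": "g3p",
   "name": "glyceraldehyde 3-phosphate"
  },
  {
   "charge": null,
   "compartment": "c",
   "formula": null,
   "id": "g6p",
   "name": "glucose 6-phosphate"
  },
  {
   "charge": null,
   "compartment": "e",
   "formula": null,
   "id": "glc_e",
   "name": "glucose (extracellular)"
  },
  {
   "charge": null,
   "compartment": "c",
   "formula": null,
   "id": "hyp",
   "name": "hypoxanthine"
  },
  {
   "charge": null,
   "compartment": "c",
   "formula": null,
   "id": "imp",
   "name": "inosine monophosphate"
  },
  {
   "charge": null,
   "compartment": "c",
   "formula": null,
   "id": "ins",
   "name": "inosine"
  },
  {
   "charge": null,
   "compartment": "c",
   "formula": null,
   "id": "prpp",
   "name": "phosphoribosyl pyrophosphate"
  },
  {
   "charge": null,
   "compartment": "c",
   "formula": null,
   "id": "pyr",
   "name": "pyruvate"
  },
  {
   "charge": null,
   "compartment": "c",
   "formula": null,
   "id": "r1p",
   "name": "ribose 1-phosphate"
  },
  {
   "charge": null,
   "compartment": "c",
   "formula": null,
   "id": "r5p",
   "name": "ribose 5-phosphate"
  },
  {
   "charge": null,
   "compartment": "c",
   "formula": null,
   "id": "ru5p",
   "name": "ribulose 5-phosphate"
  },
  {
   "charge": null,
   "compartment": "c",
   "formula": null,
   "id": "s7p",
   "name": "sedoheptulose 7-phosphate"
  },
  {
   "charge": null,
   "compartment": "c",
   "formula": null,
   "id": "x5p",
   "name": "xylulose 5-phosphate"
  }
 ],
 "objective": {
  "reaction": "BIOMASS",
  "sense": "max"
 },
 "reactions": [
  {
   "gpr": "",
   "id": "BIOMASS",
   "lower_bound": 0.0,
   "name": "biomass assembly",
   "stoichiometry": {
    "biomass": 1.0,
    "e4p": -0.1,
    "pyr": -1.0,
    "r5p": -0.5
   },
   "subsystem": "biomass",
   "upper_bound": 1.0
  },
  {
   "gpr": "",
   "id": "DM_imp",
   "lower_bound": 0.0,
   "name": "IMP demand sink",
   "stoichiometry": {
    "imp": -1.0
   },
   "subsystem": "purine",
   "upper_bound": 1000.0
  },
  {
   "gpr": "",
   "id": "EMP_LO",
   "lower_bound": 0.0,
   "name": "lumped lower glycolysis",
   "stoichiometry": {
    "g3p": -1.0,
    "pyr": 1.0
   },
   "subsystem": "EMP",
   "upper_bound": 1000.0
  },
  {
   "gpr": "",
   "id": "EX_biomass",
   "lower_bound": 0.0,
   "name": "EX_biomass",
   "stoichiometry": {
    "biomass": -1.0
   },
   "subsystem": "exchange",
   "upper_bound": 1000.0
  },
  {
   "gpr": "",
   "id": "EX_co2",
   "lower_bound": 0.0,
   "name": "EX_co2",
   "stoichiometry": {
    "co2": -1.0
   },
   "subsystem": "exchange",
   "upper_bound": 1000.0
  },
  {
   "gpr": "",
   "id": "EX_glc",
   "lower_bound": -10.0,
   "name": "EX_glc",
   "stoichiometry": {
    "glc_e": -1.0
   },
   "subsystem": "exchange",
   "upper_bound": 1000.0
  },
  {
   "gpr": "",
   "id": "EX_hyp",
   "lower_bound": 0.0,
   "name": "EX_hyp",
   "stoichiometry": {
    "hyp": -1.0
   },
   "subsystem": "exchange",
   "upper_bound": 1000.0
  },
  {
   "gpr": "",
   "id": "EX_ins",
   "lower_bound": 0.0,
   "name": "EX_ins",
   "stoichiometry": {
    "ins": -1.0
   },
   "subsystem": "exchange",
   "upper_bound": 1000.0
  },
  {
   "gpr": "",
   "id": "EX_pyr",
   "lower_bound": 0.0,
   "name": "EX_pyr",
   "stoichiometry": {
    "pyr": -1.0
   },
   "subsystem": "exchange",
   "upper_bound": 1000.0
  },
  {
   "gpr": "fbaA",
   "id": "FBA",
   "lower_bound": 0.0,
   "name": "lumped PFK/aldolase/TPI",
   "stoichiometry": {
    "f6p": -1.0,
    "g3p": 2.0
   },
   "subsystem": "EMP",
   "upper_bound": 1000.0
  },
  {
   "gpr": "glcK",
   "id": "GLK",
   "lower_bound": 0.0,
   "name": "glucokinase (lumped uptake)",
   "stoichiometry": {
    "g6p": 1.0,
    "glc_e": -1.0
   },
   "subsystem": "EMP",
   "upper_bound": 1000.0
  },
  {
   "gpr": "",
   "id": "NUC",
   "lower_bound": 0.0,
   "name": "5'-nucleotidase",
   "stoichiometry": {
    "imp": -1.0,
    "ins": 1.0
   },
   "subsystem": "purine",
   "upper_bound": 1000.0
  },
  {
   "gpr": "pgi",
   "id": "PGI",
   "lower_bound": -1000.0,
   "name": "glucose-6-phosphate isomerase",
   "stoichiometry": {
    "f6p": 1.0,
    "g6p": -1.0
   },
   "subsystem": "EMP",
   "upper_bound": 1000.0
  },
  {
   "gpr": "deoD or pupG",
   "id": "PNP",
   "lower_bound": 0.0,
   "name": "purine nucleoside phosphorylase",
   "stoichiometry": {
    "hyp": 1.0,
    "ins": -1.0,
    "r1p": 1.0
   },
   "subsystem": "purine",
   "upper_bound": 1000.0
  },
  {
   "gpr": "drm",
   "id": "PPM",
   "lower_bound": 0.5,
   "name": "phosphopentomutase (obligatory turnover backflow)",
   "stoichiometry": {
    "r1p": -1.0,
    "r5p": 1.0
   },
   "subsystem": "purine",
   "upper_bound": 1000.0
  },
  {
   "gpr": "prs",
   "id": "PRS",
   "lower_bound": 0.0,
   "name": "ribose-phosphate pyrophosphokinase",
   "stoichiometry": {
    "prpp": 1.0,
    "r5p": -1.0
   },
   "subsystem": "purine",
   "upper_bound": 1000.0
  },
  {
   "gpr": "purOp",
   "id": "PUR",
   "lower_bound": 0.0,
   "name": "lumped pur operon (de novo IMP synthesis)",
   "stoichiometry": {
    "g3p": -1.0,
    "imp": 1.0,
    "prpp": -1.0
   },
   "subsystem": "purine",
   "upper_bound": 1000.0
  },
  {
   "gpr": "",
   "id": "RPE",
   "lower_bound": -1000.0,
   "name": "ribulose-phosphate epimerase",
   "stoichiometry": {
    "ru5p": -1.0,
    "x5p": 1.0
   },
   "subsystem": "PPP",
   "upper_bound": 1000.0
  },
  {
   "gpr": "",
   "id": "RPI",
   "lower_bound": -1000.0,
   "name": "ribose-phosphate isomerase",
   "stoichiometry": {
    "r5p": 1.0,
    "ru5p": -1.0
   },
   "subsystem": "PPP",
   "upper_bound": 1000.0
  },
  {
   "gpr": "ywjH",
   "id": "TAL",
   "lower_bound": 0.3,
   "name": "transaldolase (obligatory PPP->EMP backflow)",
   "stoichiometry": {
    "e4p": 1.0,
    "f6p": 1.0,
    "g3p": -1.0,
    "s7p": -1.0
   },
   "subsystem": "PPP",
   "upper_bound": 1000.0
  },
  {
   "gpr": "tkt",
   "id": "TKT1",
   "lower_bound": 0.0,
   "name": "transketolase I",
   "stoichiometry": {
    "g3p": 1.0,
    "r5p": -1.0,
    "s7p": 1.0,
    "x5p": -1.0
   },
   "subsystem": "PPP",
   "upper_bound": 1000.0
  },
  {
   "gpr": "tkt",
   "id": "TKT2",
   "lower_bound": -1000.0,
   "name": "transketolase II",
   "stoichiometry": {
    "e4p": -1.0,
    "f6p": 1.0,
    "g3p": 1.0,
    "x5p": -1.0
   },
   "subsystem": "PPP",
   "upper_bound": 1000.0
  },
  {
   "gpr": "zwf and ykgB",
   "id": "ZWF",
   "lower_bound": 0.0,
   "name": "oxidative PPP (G6P dehydrogenase + lactonase)",
   "stoichiometry": {
    "co2": 1.0,
    "g6p": -1.0,
    "ru5p": 1.0
   },
   "subsystem": "PPP",
   "upper_bound": 1000.0
  }
 ],
 "version": 1
}
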