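"""Self-contained synthetic fixtures.

``purine_core_model`` builds a small, deterministic carbon-skeleton network
that mimics the topology relevant to purine-nucleoside overproduction in
*Bacillus subtilis*: glucose uptake, glycolysis (EMP), the oxidative and
non-oxidative pentose phosphate pathway (PPP), PRPP -> IMP -> inosine
synthesis, nucleoside degradation, and the two "backflow" nodes — the
phosphopentomutase-like reaction (gene *drm*, routing degraded ribose-1P back
into the PPP) and the transaldolase (gene *ywjH*, routing PPP carbon back to
the EMP).  Every flux consequence is hand-traceable.

Two deliberate simplifications (documented in the methods note):

* cofactors (ATP, NAD(P)H) are omitted, so stoichiometry is a pure carbon
  skeleton and yields can be checked by hand;
* the backflow reactions carry small positive *lower* bounds, modelling the
  obligatory nucleotide-turnover and PPP->EMP shunt fluxes of the wild type.
  Knocking out *drm* or *ywjH* zeroes those bounds and releases the forced
  carbon waste — which is what makes the knockouts productive, mirroring the
  biology of the engineered strains.

``random_toy_model`` produces seeded random networks with a guaranteed
nonzero-biomass backbone, used to fuzz the solver paths against oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gpr import parse_gpr
from .model import MediumSpec, MetabolicModel, Metabolite, Reaction

__all__ = [
    "ToyModelSpec",
    "purine_core_model",
    "default_medium",
    "random_toy_model",
    "thirteen_c_bounds_fixture",
]

#: forced nucleotide-turnover flux through the drm (phosphopentomutase) node
TURNOVER_FLUX = 0.5
#: forced PPP->EMP backflow through the ywjH (transaldolase) node
BACKFLOW_FLUX = 0.3
#: growth ceiling standing in for unmodelled (non-carbon) biomass requirements
GROWTH_CAP = 1.0


def _met(mid, name, comp="c"):
    return Metabolite(id=mid, name=name, compartment=comp)


def _rxn(rid, stoich, lb, ub, gpr="", subsystem=None, name=""):
    return Reaction(
        id=rid,
        name=name or rid,
        stoichiometry=stoich,
        lower_bound=lb,
        upper_bound=ub,
        gpr=parse_gpr(gpr) if gpr else None,
        subsystem=subsystem,
    )


def purine_core_model() -> MetabolicModel:
    """Deterministic EMP/PPP/purine toy model (23 reactions, 17 metabolites,
    12 genes); glucose uptake bound -10 mmol/gDW/h, growth capped at 1 /h."""
    B = 1000.0
    metabolites = [
        _met("glc_e", "glucose (extracellular)", "e"),
        _met("g6p", "glucose 6-phosphate"),
        _met("f6p", "fructose 6-phosphate"),
        _met("g3p", "glyceraldehyde 3-phosphate"),
        _met("pyr", "pyruvate"),
        _met("co2", "carbon dioxide"),
        _met("ru5p", "ribulose 5-phosphate"),
        _met("x5p", "xylulose 5-phosphate"),
        _met("r5p", "ribose 5-phosphate"),
        _met("s7p", "sedoheptulose 7-phosphate"),
        _met("e4p", "erythrose 4-phosphate"),
        _met("prpp", "phosphoribosyl pyrophosphate"),
        _met("imp", "inosine monophosphate"),
        _met("ins", "inosine"),
        _met("hyp", "hypoxanthine"),
        _met("r1p", "ribose 1-phosphate"),
        _met("biomass", "biomass"),
    ]
    reactions = [
        _rxn("EX_glc", {"glc_e": -1}, -10.0, B, subsystem="exchange"),
        _rxn("GLK", {"glc_e": -1, "g6p": 1}, 0.0, B, "glcK", "EMP", "glucokinase (lumped uptake)"),
        _rxn("PGI", {"g6p": -1, "f6p": 1}, -B, B, "pgi", "EMP", "glucose-6-phosphate isomerase"),
        _rxn("FBA", {"f6p": -1, "g3p": 2}, 0.0, B, "fbaA", "EMP", "lumped PFK/aldolase/TPI"),
        _rxn("EMP_LO", {"g3p": -1, "pyr": 1}, 0.0, B, "", "EMP", "lumped lower glycolysis"),
        _rxn("ZWF", {"g6p": -1, "ru5p": 1, "co2": 1}, 0.0, B, "zwf and ykgB", "PPP",
             "oxidative PPP (G6P dehydrogenase + lactonase)"),
        _rxn("RPE", {"ru5p": -1, "x5p": 1}, -B, B, "", "PPP", "ribulose-phosphate epimerase"),
        _rxn("RPI", {"ru5p": -1, "r5p": 1}, -B, B, "", "PPP", "ribose-phosphate isomerase"),
        _rxn("TKT1", {"x5p": -1, "r5p": -1, "s7p": 1, "g3p": 1}, 0.0, B, "tkt", "PPP",
             "transketolase I"),
        _rxn("TAL", {"s7p": -1, "g3p": -1, "e4p": 1, "f6p": 1}, BACKFLOW_FLUX, B, "ywjH",
             "PPP", "transaldolase (obligatory PPP->EMP backflow)"),
        _rxn("TKT2", {"x5p": -1, "e4p": -1, "f6p": 1, "g3p": 1}, -B, B, "tkt", "PPP",
             "transketolase II"),
        _rxn("PRS", {"r5p": -1, "prpp": 1}, 0.0, B, "prs", "purine",
             "ribose-phosphate pyrophosphokinase"),
        _rxn("PUR", {"prpp": -1, "g3p": -1, "imp": 1}, 0.0, B, "purOp", "purine",
             "lumped pur operon (de novo IMP synthesis)"),
        _rxn("NUC", {"imp": -1, "ins": 1}, 0.0, B, "", "purine", "5'-nucleotidase"),
        _rxn("PNP", {"ins": -1, "hyp": 1, "r1p": 1}, 0.0, B, "deoD or pupG", "purine",
             "purine nucleoside phosphorylase"),
        _rxn("PPM", {"r1p": -1, "r5p": 1}, TURNOVER_FLUX, B, "drm", "purine",
             "phosphopentomutase (obligatory turnover backflow)"),
        _rxn("EX_ins", {"ins": -1}, 0.0, B, subsystem="exchange"),
        _rxn("EX_hyp", {"hyp": -1}, 0.0, B, subsystem="exchange"),
        _rxn("EX_co2", {"co2": -1}, 0.0, B, subsystem="exchange"),
        _rxn("EX_pyr", {"pyr": -1}, 0.0, B, subsystem="exchange"),
        _rxn("BIOMASS", {"pyr": -1, "r5p": -0.5, "e4p": -0.1, "biomass": 1}, 0.0,
             GROWTH_CAP, "", "biomass", "biomass assembly"),
        _rxn("EX_biomass", {"biomass": -1}, 0.0, B, subsystem="exchange"),
        _rxn("DM_imp", {"imp": -1}, 0.0, B, "", "purine", "IMP demand sink"),
    ]
    genes = sorted(
        {"glcK", "pgi", "fbaA", "zwf", "ykgB", "tkt", "ywjH", "prs", "purOp",
         "deoD", "pupG", "drm"}
    )
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        objective_id="BIOMASS",
        objective_sense="max",
        id="purine_core",
    )
    model.validate()
    return model


def default_medium() -> MediumSpec:
    """Glucose minimal medium for the purine-core fixture (uptake bound -10)."""
    return MediumSpec(bounds={"EX_glc": (-10.0, 1000.0)}, default_closed=True)


@dataclass(frozen=True)
class ToyModelSpec:
    """Parameters of the random toy-model generator."""

    n_extra_reactions: int = 5
    isozyme_fraction: float = 0.3
    complex_fraction: float = 0.2
    bound_magnitude: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.isozyme_fraction <= 1.0:
            raise ValueError("isozyme_fraction must lie in [0, 1]")
        if not 0.0 <= self.complex_fraction <= 1.0:
            raise ValueError("complex_fraction must lie in [0, 1]")
        if self.n_extra_reactions < 0:
            raise ValueError("n_extra_reactions must be >= 0")


def random_toy_model(spec: ToyModelSpec) -> MetabolicModel:
    """Seeded random network with a guaranteed nonzero-biomass backbone.

    The backbone (substrate uptake -> chain -> biomass, plus a competing
    product branch with a demand sink ``DM_p``) is always present and
    unconstrained, so the model is feasible with positive growth on its
    default bounds; extra unit-coefficient conversions and random GPRs are
    layered on top.
    """
    rng = np.random.default_rng(spec.seed)
    B = float(spec.bound_magnitude)
    internal = ["m0", "m1", "m2", "p"]
    metabolites = [_met("s_e", "substrate", "e")] + [
        _met(m, m) for m in internal
    ] + [_met("bm", "biomass")]
    genes: list[str] = []

    def new_gene():
        genes.append(f"g{len(genes)}")
        return genes[-1]

    def random_gpr():
        u = rng.random()
        if u < spec.isozyme_fraction:
            return f"{new_gene()} or {new_gene()}"
        if u < spec.isozyme_fraction + spec.complex_fraction:
            return f"{new_gene()} and {new_gene()}"
        if u < 0.9:
            return new_gene()
        return ""

    reactions = [
        _rxn("EX_s", {"s_e": -1}, -10.0, B),
        _rxn("UPT", {"s_e": -1, "m0": 1}, 0.0, B, new_gene()),
        _rxn("C1", {"m0": -1, "m1": 1}, 0.0, B, new_gene()),
        _rxn("C2", {"m1": -1, "m2": 1}, 0.0, B, new_gene()),
        _rxn("P1", {"m0": -1, "p": 1}, 0.0, B, new_gene()),
        _rxn("BIO", {"m2": -1, "m1": -0.3, "bm": 1}, 0.0, B),
        _rxn("EX_bm", {"bm": -1}, 0.0, B),
        _rxn("DM_p", {"p": -1}, 0.0, B),
    ]
    pool = internal
    for k in range(spec.n_extra_reactions):
        a, b = rng.choice(len(pool), size=2, replace=False)
        reversible = rng.random() < 0.3
        reactions.append(
            _rxn(
                f"R{k}",
                {pool[a]: -1, pool[b]: 1},
                -B if reversible else 0.0,
                B,
                random_gpr(),
            )
        )
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=sorted(set(genes)),
        objective_id="BIO",
        objective_sense="max",
        id=f"toy_seed{spec.seed}",
    )
    model.validate()
    return model


def thirteen_c_bounds_fixture(model: MetabolicModel) -> dict[str, tuple[float, float]]:
    """Wild-type-like flux bounds in the style of a 13C-MFA measurement table.

    EMP fluxes are pinned to a narrow high range and the oxidative PPP entry
    to a narrow low range, as measured for glucose-grown wild-type cells; the
    table is jointly feasible with the purine-core defaults.
    """
    required = {"GLK", "FBA", "EMP_LO", "ZWF", "TAL", "PPM", "DM_imp", "EX_ins"}
    missing = required - set(model.reaction_ids)
    if missing:
        raise ValueError(f"model is not the purine-core fixture; missing {sorted(missing)}")
    return {
        "GLK": (8.0, 9.5),
        "FBA": (5.0, 9.0),
        "EMP_LO": (8.0, 14.0),
        "ZWF": (0.5, 1.5),
        "TAL": (0.3, 0.6),
        "PPM": (0.5, 0.8),
        "DM_imp": (0.0, 0.2),
        "EX_ins": (0.0, 0.1),
    }
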