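"""Stoichiometric model domain types: metabolites, reactions, models, media.

Units follow the constraint-based convention: fluxes in mmol/gDW/h, growth
(the biomass reaction flux) in 1/h.  Exchange reactions are written with a
single metabolite at coefficient -1 (``1 M ->``); negative flux is uptake,
positive flux is secretion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from .gpr import GprExpression, format_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "MediumSpec",
    "ModelValidationError",
    "apply_medium",
    "knockout_genes",
    "knockout_reactions",
]

#: conventional "unbounded" sentinel for freely exchanged species
FREE_BOUND = 1000.0


class ModelValidationError(ValueError):
    """Aggregates all validation problems found in a model."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None


@dataclass(frozen=True)
class Reaction:
    """A bounded, possibly gene-associated reaction column of S."""

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = -FREE_BOUND
    upper_bound: float = FREE_BOUND
    name: str = ""
    gpr: GprExpression | None = None
    subsystem: str | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "stoichiometry", {k: float(v) for k, v in self.stoichiometry.items()}
        )

    @property
    def is_exchange(self) -> bool:
        """Boundary convention: exactly one metabolite, coefficient -1."""
        if len(self.stoichiometry) != 1:
            return False
        (coeff,) = self.stoichiometry.values()
        return coeff == -1

    @property
    def gpr_string(self) -> str:
        return format_gpr(self.gpr)

    def equation(self, arrow: str = "<=>") -> str:
        """Human-readable equation string, substrates -> products."""
        subs = [(m, -c) for m, c in sorted(self.stoichiometry.items()) if c < 0]
        prods = [(m, c) for m, c in sorted(self.stoichiometry.items()) if c > 0]
        if self.lower_bound >= 0:
            arrow = "-->"
        elif self.upper_bound <= 0:
            arrow = "<--"

        def side(terms):
            return " + ".join(f"{c:g} {m}" if c != 1 else m for m, c in terms)

        return f"{side(subs)} {arrow} {side(prods)}".strip()


@dataclass
class MetabolicModel:
    """A stoichiometric network with bounds, GPRs and a flux objective."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str]
    objective_id: str
    objective_sense: str = "max"
    id: str = "model"

    # -- indexing -----------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"unknown reaction {rxn_id!r}")

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"unknown metabolite {met_id!r}")

    def reaction_index(self) -> dict[str, int]:
        return {r.id: j for j, r in enumerate(self.reactions)}

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S with one row per metabolite, one column per reaction."""
        met_idx = {m.id: i for i, m in enumerate(self.metabolites)}
        rows, cols, data = [], [], []
        for j, r in enumerate(self.reactions):
            for met, coeff in r.stoichiometry.items():
                rows.append(met_idx[met])
                cols.append(j)
                data.append(float(coeff))
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check all structural invariants; raise listing every offender."""
        problems: list[str] = []
        met_ids = self.metabolite_ids
        seen = set()
        for mid in met_ids:
            if mid in seen:
                problems.append(f"duplicate metabolite id {mid!r}")
            seen.add(mid)
        for m in self.metabolites:
            if not m.compartment:
                problems.append(f"metabolite {m.id!r} has empty compartment")
        met_set = set(met_ids)
        seen = set()
        gene_set = set(self.genes)
        for r in self.reactions:
            if r.id in seen:
                problems.append(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            if not r.stoichiometry:
                problems.append(f"reaction {r.id!r} has empty stoichiometry")
            for met in r.stoichiometry:
                if met not in met_set:
                    problems.append(f"reaction {r.id!r} references unknown metabolite {met!r}")
            if r.lower_bound > r.upper_bound:
                problems.append(
                    f"reaction {r.id!r} has lower_bound {r.lower_bound} > upper_bound {r.upper_bound}"
                )
            if r.gpr is not None:
                missing = r.gpr.genes - gene_set
                if missing:
                    problems.append(
                        f"reaction {r.id!r} GPR references unlisted genes {sorted(missing)}"
                    )
        if self.objective_id not in {r.id for r in self.reactions}:
            problems.append(f"objective reaction {self.objective_id!r} not in model")
        if self.objective_sense not in {"max", "min"}:
            problems.append(f"objective_sense must be max|min, got {self.objective_sense!r}")
        if problems:
            raise ModelValidationError(problems)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            genes=list(self.genes),
            objective_id=self.objective_id,
            objective_sense=self.objective_sense,
            id=self.id,
        )

    def with_bounds(self, bounds: Mapping[str, tuple[float, float]]) -> "MetabolicModel":
        """Copy with selected reactions' bounds replaced."""
        unknown = set(bounds) - set(self.reaction_ids)
        if unknown:
            raise KeyError(f"unknown reactions: {sorted(unknown)}")
        new = self.copy()
        new.reactions = [
            replace(r, lower_bound=bounds[r.id][0], upper_bound=bounds[r.id][1])
            if r.id in bounds
            else r
            for r in self.reactions
        ]
        return new

    # -- canonical form and equality ---------------------------------------

    def to_canonical_dict(self) -> dict:
        """Order-independent canonical representation (sorted ids).

        Used for serialisation and equality: two models are equal iff their
        canonical dicts are equal, regardless of list ordering.
        """

        def enc_bound(x: float):
            if math.isinf(x):
                return "inf" if x > 0 else "-inf"
            return x

        return {
            "id": self.id,
            "objective": {"reaction": self.objective_id, "sense": self.objective_sense},
            "genes": sorted(self.genes),
            "metabolites": [
                {
                    "id": m.id,
                    "name": m.name,
                    "compartment": m.compartment,
                    "formula": m.formula,
                    "charge": m.charge,
                }
                for m in sorted(self.metabolites, key=lambda m: m.id)
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                    "lower_bound": enc_bound(r.lower_bound),
                    "upper_bound": enc_bound(r.upper_bound),
                    "gpr": r.gpr_string,
                    "subsystem": r.subsystem,
                }
                for r in sorted(self.reactions, key=lambda r: r.id)
            ],
        }

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return self.to_canonical_dict() == other.to_canonical_dict()


@dataclass(frozen=True)
class MediumSpec:
    """Exchange-reaction bounds defining the growth medium.

    With ``default_closed`` (the default), every exchange reaction *not*
    listed gets its uptake shut off (lower bound raised to 0); secretion
    bounds are left untouched.
    """

    bounds: Mapping[str, tuple[float, float]]
    default_closed: bool = True

    def __post_init__(self):
        object.__setattr__(self, "bounds", dict(self.bounds))


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy of ``model`` with exchange bounds set from ``medium``."""
    exchange_ids = {r.id for r in model.exchanges}
    unknown = set(medium.bounds) - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"medium references unknown reactions: {sorted(unknown)}")
    non_exchange = set(medium.bounds) - exchange_ids
    if non_exchange:
        raise ValueError(f"medium references non-exchange reactions: {sorted(non_exchange)}")
    new_bounds: dict[str, tuple[float, float]] = {}
    for rid, (lb, ub) in medium.bounds.items():
        new_bounds[rid] = (float(lb), float(ub))
    if medium.default_closed:
        for r in model.exchanges:
            if r.id not in medium.bounds and r.lower_bound < 0:
                new_bounds[r.id] = (0.0, r.upper_bound)
    return model.with_bounds(new_bounds)


def knockout_genes(model: MetabolicModel, genes: Iterable[str]) -> MetabolicModel:
    """Zero the bounds of every reaction whose GPR fails under the knockout.

    Reactions without a GPR, or whose rule survives (e.g. an isozyme remains),
    are untouched.  Unknown genes raise.
    """
    knocked = set(genes)
    unknown = knocked - set(model.genes)
    if unknown:
        raise KeyError(f"unknown genes: {sorted(unknown)}")
    new_bounds = {
        r.id: (0.0, 0.0)
        for r in model.reactions
        if r.gpr is not None and not r.gpr.evaluate(knocked)
    }
    return model.with_bounds(new_bounds)


def knockout_reactions(model: MetabolicModel, rxn_ids: Iterable[str]) -> MetabolicModel:
    """Set the bounds of the listed reactions to (0, 0)."""
    ids = set(rxn_ids)
    unknown = ids - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"unknown reactions: {sorted(unknown)}")
    return model.with_bounds({rid: (0.0, 0.0) for rid in ids})


def reactions_disabled_by(model: MetabolicModel, genes: Iterable[str]) -> set[str]:
    """Reaction ids whose GPR evaluates false under the knockout set."""
    knocked = set(genes)
    return {
        r.id
        for r in model.reactions
        if r.gpr is not None and not r.gpr.evaluate(knocked)
    }
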