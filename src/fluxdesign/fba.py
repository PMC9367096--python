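"""Linear-programming flux analyses.

Flux balance analysis (FBA) maximises a linear flux objective c'v over the
steady-state polytope {v : S v = 0, vmin <= v <= vmax}.  On top of the plain
solve this module provides flux variability analysis (FVA), molar product
yield, the biomass-vs-product production envelope (robustness curve), and the
combined theoretical-maxima summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from ._solver import INFEASIBLE, OPTIMAL, LpResult, solve_lp
from .model import MetabolicModel

__all__ = [
    "FluxSolution",
    "RobustnessCurve",
    "TheoreticalMaxima",
    "UndefinedYieldError",
    "solve_fba",
    "yield_mol_per_mol",
    "flux_variability",
    "production_envelope",
    "theoretical_maxima",
]

#: default feasibility tolerance used in invariant checks
FEASIBILITY_TOL = 1e-9
#: default relative tolerance for comparing objective values
OPTIMALITY_RTOL = 1e-6


@dataclass
class FluxSolution:
    """One LP outcome: status, optimal value, and a (possibly degenerate)
    optimal flux vector keyed by reaction id."""

    status: str
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


@dataclass
class RobustnessCurve:
    """Attainable target-flux range as a function of fixed growth rate."""

    growth_grid: list[float]
    max_target: list[float]
    min_target: list[float]

    def __post_init__(self):
        if not (len(self.growth_grid) == len(self.max_target) == len(self.min_target)):
            raise ValueError("robustness curve lists must have equal length")


@dataclass(frozen=True)
class TheoreticalMaxima:
    """Maximum growth rate, maximum target synthesis rate, and the molar
    yield of the target on the substrate at that maximum."""

    mu_max: float
    target_max: float
    yield_at_target_max: float | None


class UndefinedYieldError(ValueError):
    pass


def _lp_arrays(model: MetabolicModel):
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    return S, list(zip(lb, ub))


def _objective_vector(model: MetabolicModel, objective_id: str) -> np.ndarray:
    c = np.zeros(len(model.reactions))
    c[model.reaction_index()[objective_id]] = 1.0
    return c


def solve_fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    sense: str | None = None,
) -> FluxSolution:
    """Solve the FBA linear program.

    Defaults to the model's own objective reaction and sense.  Infeasible or
    unbounded problems are reported through ``status``, never raised.
    """
    objective_id = objective_id or model.objective_id
    sense = sense or model.objective_sense
    if objective_id not in set(model.reaction_ids):
        raise KeyError(f"unknown objective reaction {objective_id!r}")
    S, bounds = _lp_arrays(model)
    c = _objective_vector(model, objective_id)
    res = solve_lp(c, S, np.zeros(S.shape[0]), None, None, bounds, sense=sense)
    if not res.status == OPTIMAL:
        return FluxSolution(res.status, None)
    fluxes = dict(zip(model.reaction_ids, res.x.tolist()))
    return FluxSolution(OPTIMAL, float(res.objective), fluxes)


def yield_mol_per_mol(
    solution: FluxSolution, target_id: str, substrate_exchange_id: str
) -> float:
    """Molar yield v_target / |v_substrate| from one flux solution.

    The substrate exchange must carry uptake (negative flux); zero uptake
    makes the yield undefined.
    """
    if not solution.optimal:
        raise UndefinedYieldError("yield requires an optimal flux solution")
    v_s = solution.fluxes[substrate_exchange_id]
    if v_s >= 0:
        raise UndefinedYieldError(
            f"substrate exchange {substrate_exchange_id!r} carries no uptake (flux {v_s:g})"
        )
    return solution.fluxes[target_id] / abs(v_s)


def flux_variability(
    model: MetabolicModel,
    rxn_ids: list[str] | None = None,
    fraction_of_optimum: float = 1.0,
) -> dict[str, tuple[float, float]]:
    """Per-reaction flux ranges subject to objective >= fraction * optimum.

    With ``fraction_of_optimum=0`` the objective floor is dropped and the
    ranges are those of the raw steady-state polytope.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    rxn_ids = list(rxn_ids) if rxn_ids is not None else model.reaction_ids
    idx = model.reaction_index()
    unknown = [r for r in rxn_ids if r not in idx]
    if unknown:
        raise KeyError(f"unknown reactions: {unknown}")
    S, bounds = _lp_arrays(model)
    b_eq = np.zeros(S.shape[0])
    A_ub = None
    b_ub = None
    if fraction_of_optimum > 0.0:
        base = solve_fba(model)
        if not base.optimal:
            raise RuntimeError(f"model is {base.status}; cannot run FVA")
        c_obj = _objective_vector(model, model.objective_id)
        floor = fraction_of_optimum * base.objective_value
        if model.objective_sense == "max":
            A_ub = sparse.csr_matrix(-c_obj)
            b_ub = np.array([-floor])
        else:
            A_ub = sparse.csr_matrix(c_obj)
            b_ub = np.array([floor])
    ranges: dict[str, tuple[float, float]] = {}
    n = len(model.reactions)
    for rid in rxn_ids:
        c = np.zeros(n)
        c[idx[rid]] = 1.0
        lo = solve_lp(c, S, b_eq, A_ub, b_ub, bounds, sense="min")
        hi = solve_lp(c, S, b_eq, A_ub, b_ub, bounds, sense="max")
        if lo.status != OPTIMAL or hi.status != OPTIMAL:
            raise RuntimeError(f"FVA subproblem for {rid!r} was {lo.status}/{hi.status}")
        ranges[rid] = (float(lo.objective), float(hi.objective))
    return ranges


def production_envelope(
    model: MetabolicModel,
    biomass_id: str | None = None,
    target_id: str | None = None,
    n_points: int = 20,
) -> RobustnessCurve:
    """Min/max target flux over a uniform growth grid spanning [0, mu_max].

    The upper boundary of the returned curve is piecewise-linear and concave
    (a parametric-LP property); both endpoints are included.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    biomass_id = biomass_id or model.objective_id
    target_id = target_id or model.objective_id
    mu = solve_fba(model, biomass_id, "max")
    if not mu.optimal:
        raise RuntimeError(f"model is {mu.status}; cannot build envelope")
    mu_max = mu.objective_value
    idx = model.reaction_index()
    S, bounds = _lp_arrays(model)
    b_eq = np.zeros(S.shape[0])
    c = np.zeros(len(model.reactions))
    c[idx[target_id]] = 1.0
    j_bio = idx[biomass_id]
    grid = np.linspace(0.0, mu_max, n_points)
    lo_orig = bounds[j_bio]
    max_t, min_t = [], []
    for g in grid:
        bounds[j_bio] = (g, g)
        hi = solve_lp(c, S, b_eq, None, None, bounds, sense="max")
        lo = solve_lp(c, S, b_eq, None, None, bounds, sense="min")
        if hi.status != OPTIMAL or lo.status != OPTIMAL:
            raise RuntimeError(f"envelope infeasible at growth {g:g}")
        max_t.append(float(hi.objective))
        min_t.append(float(lo.objective))
    bounds[j_bio] = lo_orig
    return RobustnessCurve(list(map(float, grid)), max_t, min_t)


def theoretical_maxima(
    model: MetabolicModel,
    biomass_id: str,
    target_id: str,
    substrate_id: str,
    growth_fixed: float | None = None,
) -> TheoreticalMaxima:
    """Maximum growth, maximum target synthesis rate, and its molar yield.

    ``growth_fixed`` optionally pins the growth rate (e.g. 0) during the
    target maximisation; by default growth is left free, so the target
    maximum is the unconstrained LP optimum.
    """
    mu = solve_fba(model, biomass_id, "max")
    if not mu.optimal:
        raise RuntimeError(f"model is {mu.status}")
    work = model
    if growth_fixed is not None:
        work = model.with_bounds({biomass_id: (growth_fixed, growth_fixed)})
    tgt = solve_fba(work, target_id, "max")
    if not tgt.optimal:
        raise RuntimeError(f"target maximisation is {tgt.status}")
    try:
        y = yield_mol_per_mol(tgt, target_id, substrate_id)
    except UndefinedYieldError:
        y = None
    return TheoreticalMaxima(float(mu.objective_value), float(tgt.objective_value), y)
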