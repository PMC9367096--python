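"""Regulatory on/off minimisation (ROOM).

After a knockout, ROOM postulates that the cell reaches the steady flux state
that changes the *fewest* reactions relative to a wild-type reference vector
w.  A reaction i counts as changed (binary y_i = 1) when its flux leaves the
tolerance window

    w_i^l = w_i - delta*|w_i| - eps   <=   v_i   <=   w_i + delta*|w_i| + eps = w_i^u

and the MILP minimises sum_i y_i subject to steady state, the model bounds,
forced-zero knockouts (v_j = 0 for j in A), and big-M window constraints that
use the model's own bounds as big-M:

    v_i - y_i (vmax_i - w_i^u) <= w_i^u
    v_i - y_i (vmin_i - w_i^l) >= w_i^l

Secondary quantities (growth, target flux) are read from the ROOM-optimal
face by lexicographic re-optimisation: fix sum(y) at its minimum, maximise
growth, then fix growth and maximise the target.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from ._solver import INFEASIBLE, OPTIMAL, solve_lp, solve_milp
from .fba import RobustnessCurve, solve_fba
from .model import MetabolicModel, reactions_disabled_by

__all__ = [
    "RoomConfig",
    "RoomResult",
    "reference_flux",
    "solve_room",
    "assess_strategy",
]

log = logging.getLogger(__name__)

#: canonical ROOM thresholds
DEFAULT_DELTA = 0.03
DEFAULT_EPSILON = 0.001


@dataclass(frozen=True)
class RoomConfig:
    """Reference flux vector w, thresholds, and the forced-zero set A."""

    reference_flux: dict[str, float]
    delta: float = DEFAULT_DELTA
    epsilon: float = DEFAULT_EPSILON
    forced_zero: frozenset[str] = frozenset()
    relaxed: bool = False

    def __post_init__(self):
        if self.delta < 0 or self.epsilon < 0:
            raise ValueError("delta and epsilon must be >= 0")
        object.__setattr__(self, "forced_zero", frozenset(self.forced_zero))
        object.__setattr__(self, "reference_flux", dict(self.reference_flux))

    def window(self, w: float) -> tuple[float, float]:
        half = self.delta * abs(w) + self.epsilon
        return (w - half, w + half)


@dataclass
class RoomResult:
    status: str
    n_changed: int | None
    changed_set: frozenset[str] = frozenset()
    fluxes: dict[str, float] = field(default_factory=dict)
    growth: float | None = None
    target_flux: float | None = None
    target_range: tuple[float, float] | None = None

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


def reference_flux(
    model: MetabolicModel,
    mode: str = "fba_parsimonious",
    table: dict[str, float] | None = None,
) -> dict[str, float]:
    """Wild-type reference flux vector w.

    ``fba`` returns one biomass-optimal vector (degenerate in general);
    ``fba_parsimonious`` additionally minimises total absolute flux at the
    fixed optimum, which makes w reproducible; ``table`` echoes a measured
    (e.g. 13C-derived) vector and requires every model reaction to be listed.
    """
    if mode == "table":
        if table is None:
            raise ValueError("table mode requires a flux table")
        gaps = sorted(set(model.reaction_ids) - set(table))
        if gaps:
            raise ValueError(f"flux table missing reactions: {gaps}")
        return {rid: float(table[rid]) for rid in model.reaction_ids}
    sol = solve_fba(model)
    if not sol.optimal:
        raise RuntimeError(f"model is {sol.status}; no reference flux")
    if mode == "fba":
        return dict(sol.fluxes)
    if mode != "fba_parsimonious":
        raise ValueError(f"unknown reference mode {mode!r}")
    # min sum |v| at fixed optimum: auxiliary t_i >= |v_i|, minimise sum t
    n = len(model.reactions)
    S = model.stoichiometric_matrix()
    A_eq = sparse.hstack([S, sparse.csr_matrix((S.shape[0], n))]).tocsr()
    b_eq = np.zeros(S.shape[0])
    lb, ub = model.bounds_arrays()
    big = np.maximum(np.abs(lb), np.abs(ub))
    bounds = list(zip(lb, ub)) + [(0.0, float(b)) for b in big]
    eye = sparse.identity(n, format="csr")
    rows = [sparse.hstack([eye, -eye]), sparse.hstack([-eye, -eye])]
    b_rows = [np.zeros(n), np.zeros(n)]
    j = model.reaction_index()[model.objective_id]
    c_obj = np.zeros(2 * n)
    c_obj[j] = 1.0
    opt = sol.objective_value
    sign = 1.0 if model.objective_sense == "max" else -1.0
    rows.append(sparse.csr_matrix(-sign * c_obj))
    b_rows.append(np.array([-sign * (opt - 1e-9 * max(1.0, abs(opt)))]))
    A_ub = sparse.vstack(rows).tocsr()
    b_ub = np.concatenate(b_rows)
    c = np.concatenate([np.zeros(n), np.ones(n)])
    res = solve_lp(c, A_eq, b_eq, A_ub, b_ub, bounds, sense="min")
    if res.status != OPTIMAL:
        raise RuntimeError(f"parsimonious reference LP is {res.status}")
    return dict(zip(model.reaction_ids, res.x[:n].tolist()))


def _room_milp(
    model: MetabolicModel,
    config: RoomConfig,
    objective: np.ndarray | None = None,
    sense: str = "min",
    extra_rows: list[tuple[dict[int, float], float, float]] = (),
):
    """Shared MILP builder: variables v(n) then y(n); default objective sum(y)."""
    n = len(model.reactions)
    m = len(model.metabolites)
    idx = model.reaction_index()
    w = np.array([config.reference_flux.get(rid, 0.0) for rid in model.reaction_ids])
    missing = set(model.reaction_ids) - set(config.reference_flux)
    if missing:
        raise ValueError(f"reference flux missing reactions: {sorted(missing)}")
    lb, ub = model.bounds_arrays()
    for rid in config.forced_zero:
        jz = idx[rid]
        lb[jz], ub[jz] = 0.0, 0.0
    wu = w + config.delta * np.abs(w) + config.epsilon
    wl = w - config.delta * np.abs(w) - config.epsilon

    rows: list[dict[int, float]] = []
    rlo: list[float] = []
    rhi: list[float] = []
    S = model.stoichiometric_matrix().tocoo()
    srows: dict[int, dict[int, float]] = {i: {} for i in range(m)}
    for i, jj, val in zip(S.row, S.col, S.data):
        srows[i][jj] = val
    for i in range(m):
        rows.append(srows[i])
        rlo.append(0.0)
        rhi.append(0.0)
    for i in range(n):
        # v_i - y_i (vmax_i - wu_i) <= wu_i ; v_i - y_i (vmin_i - wl_i) >= wl_i
        rows.append({i: 1.0, n + i: -(ub[i] - wu[i])})
        rlo.append(-np.inf)
        rhi.append(wu[i])
        rows.append({i: 1.0, n + i: -(lb[i] - wl[i])})
        rlo.append(wl[i])
        rhi.append(np.inf)
    for row, lo_v, hi_v in extra_rows:
        rows.append(row)
        rlo.append(lo_v)
        rhi.append(hi_v)

    data, ri, ci = [], [], []
    for i, row in enumerate(rows):
        for jj, val in row.items():
            ri.append(i)
            ci.append(jj)
            data.append(val)
    A = sparse.csr_matrix((data, (ri, ci)), shape=(len(rows), 2 * n))
    bounds_lo = np.concatenate([lb, np.zeros(n)])
    bounds_hi = np.concatenate([ub, np.ones(n)])
    integrality = np.concatenate([np.zeros(n), np.zeros(n) if config.relaxed else np.ones(n)])
    if objective is None:
        objective = np.concatenate([np.zeros(n), np.ones(n)])
    return solve_milp(objective, A, np.array(rlo), np.array(rhi),
                      bounds_lo, bounds_hi, integrality, sense=sense)


def solve_room(
    model: MetabolicModel,
    config: RoomConfig,
    growth_id: str | None = None,
    target_id: str | None = None,
) -> RoomResult:
    """Minimise the number of significantly changed reactions after a knockout.

    Growth and target flux are reported by lexicographic re-optimisation over
    the ROOM-optimal solution set (see module docstring); ``target_range``
    carries the min/max target flux over that face.
    """
    n = len(model.reactions)
    growth_id = growth_id or model.objective_id
    res = _room_milp(model, config)
    if res.status != OPTIMAL:
        return RoomResult(status=res.status, n_changed=None)
    n_changed = int(round(res.objective)) if not config.relaxed else res.objective
    idx = model.reaction_index()

    # lexicographic: fix sum(y), maximise growth
    y_row = ({n + i: 1.0 for i in range(n)}, -np.inf, float(res.objective) + 1e-6)
    c_growth = np.zeros(2 * n)
    c_growth[idx[growth_id]] = 1.0
    res2 = _room_milp(model, config, objective=c_growth, sense="max", extra_rows=[y_row])
    if res2.status != OPTIMAL:  # pragma: no cover - fallback to first solve
        res2 = res
    growth = float(res2.x[idx[growth_id]])

    target_flux = None
    target_range = None
    v = res2.x[:n]
    if target_id is not None:
        g_row = ({idx[growth_id]: 1.0}, growth - 1e-6 * max(1.0, abs(growth)), np.inf)
        c_t = np.zeros(2 * n)
        c_t[idx[target_id]] = 1.0
        hi = _room_milp(model, config, objective=c_t, sense="max", extra_rows=[y_row, g_row])
        lo = _room_milp(model, config, objective=c_t, sense="min", extra_rows=[y_row, g_row])
        if hi.status == OPTIMAL and lo.status == OPTIMAL:
            target_range = (float(lo.objective), float(hi.objective))
            target_flux = float(hi.objective)
            v = hi.x[:n]
    fluxes = dict(zip(model.reaction_ids, v.tolist()))
    changed = frozenset(
        rid
        for rid, val in fluxes.items()
        if not (
            config.window(config.reference_flux.get(rid, 0.0))[0] - 1e-7
            <= val
            <= config.window(config.reference_flux.get(rid, 0.0))[1] + 1e-7
        )
    )
    return RoomResult(
        status=OPTIMAL,
        n_changed=n_changed,
        changed_set=changed,
        fluxes=fluxes,
        growth=growth,
        target_flux=target_flux,
        target_range=target_range,
    )


def assess_strategy(
    model: MetabolicModel,
    knocked_genes: frozenset[str] | set[str],
    growth_grid: list[float],
    target_id: str,
    reference: dict[str, float] | None = None,
    delta: float = DEFAULT_DELTA,
    epsilon: float = DEFAULT_EPSILON,
    growth_id: str | None = None,
) -> RobustnessCurve:
    """Min/max target flux over ROOM-optimal states at each fixed growth rate.

    The knockout strategy's disabled reactions form the forced-zero set A;
    at every grid growth rate the ROOM MILP is solved with growth pinned,
    then the target flux is min/maxed at the ROOM optimum.  Infeasible grid
    points are marked with NaN rather than aborting the curve.
    """
    growth_id = growth_id or model.objective_id
    if reference is None:
        reference = reference_flux(model, "fba_parsimonious")
    forced = frozenset(reactions_disabled_by(model, set(knocked_genes)))
    config = RoomConfig(
        reference_flux=reference, delta=delta, epsilon=epsilon, forced_zero=forced
    )
    n = len(model.reactions)
    idx = model.reaction_index()
    max_t: list[float] = []
    min_t: list[float] = []
    for g in growth_grid:
        g_row = ({idx[growth_id]: 1.0}, g, g)
        base = _room_milp(model, config, extra_rows=[g_row])
        if base.status != OPTIMAL:
            max_t.append(math.nan)
            min_t.append(math.nan)
            continue
        y_row = ({n + i: 1.0 for i in range(n)}, -np.inf, float(base.objective) + 1e-6)
        c_t = np.zeros(2 * n)
        c_t[idx[target_id]] = 1.0
        hi = _room_milp(model, config, objective=c_t, sense="max", extra_rows=[g_row, y_row])
        lo = _room_milp(model, config, objective=c_t, sense="min", extra_rows=[g_row, y_row])
        max_t.append(float(hi.objective) if hi.status == OPTIMAL else math.nan)
        min_t.append(float(lo.objective) if lo.status == OPTIMAL else math.nan)
    return RobustnessCurve(list(map(float, growth_grid)), max_t, min_t)
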