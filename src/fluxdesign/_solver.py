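"""Thin wrappers around scipy's HiGHS LP/MILP interfaces.

All optimisation in the package funnels through these two helpers so that
solver options and status mapping live in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, sparse

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
FAILED = "failed"

_LP_STATUS = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}


@dataclass
class LpResult:
    status: str
    objective: float | None
    x: np.ndarray | None


def solve_lp(
    c: np.ndarray,
    A_eq: sparse.spmatrix | None,
    b_eq: np.ndarray | None,
    A_ub: sparse.spmatrix | None,
    b_ub: np.ndarray | None,
    bounds: list[tuple[float, float]],
    sense: str = "min",
) -> LpResult:
    """Solve an LP with HiGHS; ``sense`` flips the objective, the reported
    objective value is always in the caller's sense."""
    sign = -1.0 if sense == "max" else 1.0
    res = optimize.linprog(
        sign * np.asarray(c, dtype=float),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    status = _LP_STATUS.get(res.status, FAILED)
    if status != OPTIMAL:
        return LpResult(status, None, None)
    return LpResult(OPTIMAL, sign * res.fun, res.x)


def solve_milp(
    c: np.ndarray,
    A: sparse.spmatrix,
    lb_con: np.ndarray,
    ub_con: np.ndarray,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    integrality: np.ndarray,
    sense: str = "min",
    time_limit: float | None = None,
) -> LpResult:
    """Solve a MILP with HiGHS via ``scipy.optimize.milp``."""
    sign = -1.0 if sense == "max" else 1.0
    options = {}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = optimize.milp(
        sign * np.asarray(c, dtype=float),
        constraints=optimize.LinearConstraint(A, lb_con, ub_con),
        bounds=optimize.Bounds(bounds_lo, bounds_hi),
        integrality=integrality,
        options=options,
    )
    if res.status == 0 and res.x is not None:
        return LpResult(OPTIMAL, sign * res.fun, res.x)
    if res.status == 2:
        return LpResult(INFEASIBLE, None, None)
    if res.status == 3:
        return LpResult(UNBOUNDED, None, None)
    return LpResult(FAILED, None, None)
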