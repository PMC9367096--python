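"""Independent oracles used by the test suite.

These deliberately avoid the package's solver path:

* ``simplex_solve`` is a dense two-phase tableau simplex (Bland's rule) on an
  explicitly written standard-form tableau — an independent LP formulation
  and an independent pivoting algorithm;
* ``room_exhaustive_min`` enumerates binary on/off assignments in ascending
  cardinality and checks each with an LP feasibility problem;
* truth-table GPR evaluation is done inline in the tests.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize


def simplex_solve(c, S, lb, ub, sense="max"):
    """Solve max/min c'v s.t. S v = 0, lb <= v <= ub with a dense two-phase
    tableau simplex.  Returns (status, objective, v).

    Standard form: x = v - lb >= 0; rows are S x = -S lb and x + s = ub - lb.
    All bounds must be finite.
    """
    c = np.asarray(c, float)
    S = np.asarray(S, float)
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    if not (np.isfinite(lb).all() and np.isfinite(ub).all()):
        raise ValueError("simplex oracle requires finite bounds")
    m, n = S.shape
    u = ub - lb
    A = np.zeros((m + n, n + n))
    b = np.zeros(m + n)
    A[:m, :n] = S
    b[:m] = -S @ lb
    A[m:, :n] = np.eye(n)
    A[m:, n:] = np.eye(n)
    b[m:] = u
    obj = np.zeros(n + n)
    obj[:n] = c if sense == "max" else -c
    status, val, x = _two_phase(A, b, obj)
    if status != "optimal":
        return status, None, None
    v = x[:n] + lb
    objective = c @ v
    return "optimal", objective, v


def _two_phase(A, b, c, tol=1e-9, max_iter=20000):
    """Maximise c'x s.t. A x = b, x >= 0 (two-phase, Bland's rule)."""
    m, n = A.shape
    A = A.copy()
    b = b.copy()
    neg = b < 0
    A[neg] *= -1
    b[neg] *= -1
    # phase 1: artificial basis
    T = np.zeros((m + 1, n + m + 1))
    T[:m, :n] = A
    T[:m, n : n + m] = np.eye(m)
    T[:m, -1] = b
    T[m, n : n + m] = 1.0
    T[m] -= T[:m].sum(axis=0)  # price out artificials
    basis = list(range(n, n + m))
    if not _iterate(T, basis, tol, max_iter):
        return "failed", None, None
    if T[m, -1] < -1e-7:
        return "infeasible", None, None
    # drive any artificial variables out of the basis
    for i, bi in enumerate(basis):
        if bi >= n:
            row = T[i, :n]
            piv = np.where(np.abs(row) > tol)[0]
            if piv.size:
                _pivot(T, i, piv[0])
                basis[i] = piv[0]
    # phase 2
    T2 = np.zeros((m + 1, n + 1))
    T2[:m, :n] = T[:m, :n]
    T2[:m, -1] = T[:m, -1]
    T2[m, :n] = -c
    for i, bi in enumerate(basis):
        if bi < n:
            T2[m] -= T2[m, bi] * T2[i]
    if not _iterate(T2, basis, tol, max_iter):
        return "unbounded", None, None
    x = np.zeros(n)
    for i, bi in enumerate(basis):
        if bi < n:
            x[bi] = T2[i, -1]
    return "optimal", T2[m, -1], x


def _iterate(T, basis, tol, max_iter):
    m = T.shape[0] - 1
    for _ in range(max_iter):
        cost = T[m, :-1]
        entering = np.where(cost < -tol)[0]
        if entering.size == 0:
            return True
        j = entering[0]  # Bland's rule
        col = T[:m, j]
        pos = col > tol
        if not pos.any():
            return False  # unbounded
        ratios = np.full(m, np.inf)
        ratios[pos] = T[:m, -1][pos] / col[pos]
        # Bland tie-break: smallest ratio, then smallest basis index
        best = np.min(ratios)
        rows = [i for i in range(m) if ratios[i] <= best + tol]
        i = min(rows, key=lambda r: basis[r])
        _pivot(T, i, j)
        basis[i] = j
    raise RuntimeError("simplex iteration limit reached")


def _pivot(T, i, j):
    T[i] /= T[i, j]
    for r in range(T.shape[0]):
        if r != i:
            T[r] -= T[r, j] * T[i]


def fba_oracle(model, objective_id, sense="max"):
    """Dense-simplex FBA objective for a fluxdesign model (finite bounds)."""
    S = model.stoichiometric_matrix().toarray()
    lb, ub = model.bounds_arrays()
    c = np.zeros(len(model.reactions))
    c[model.reaction_index()[objective_id]] = 1.0
    return simplex_solve(c, S, lb, ub, sense=sense)


def room_exhaustive_min(model, config, max_changed=6):
    """Exhaustive ROOM minimum: smallest number of off-window reactions.

    Enumerates changed-sets by ascending cardinality; each assignment is an
    LP feasibility check (windows clamped for unchanged reactions, knocked
    reactions forced to zero).  Returns the minimum count or None when no
    assignment up to ``max_changed`` is feasible.
    """
    ids = model.reaction_ids
    n = len(ids)
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    idx = model.reaction_index()
    for rid in config.forced_zero:
        lb[idx[rid]], ub[idx[rid]] = 0.0, 0.0

    def feasible(changed):
        lo = lb.copy()
        hi = ub.copy()
        for i, rid in enumerate(ids):
            if i in changed:
                continue
            wlo, whi = config.window(config.reference_flux.get(rid, 0.0))
            lo[i] = max(lo[i], wlo)
            hi[i] = min(hi[i], whi)
            if lo[i] > hi[i] + 1e-12:
                return False
        res = optimize.linprog(
            np.zeros(n), A_eq=S, b_eq=np.zeros(S.shape[0]),
            bounds=list(zip(lo, np.maximum(lo, hi))), method="highs",
        )
        return res.status == 0

    for k in range(0, min(n, max_changed) + 1):
        for combo in itertools.combinations(range(n), k):
            if feasible(set(combo)):
                return k
    return None
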