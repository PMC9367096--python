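"""Knockout strain design.

GDLS (genetic design through local search) searches for gene-knockout sets
that maximise a target flux (outer objective) while the cell is assumed to
maximise growth (inner objective).  The bi-level program

    max_y  g'v   s.t.  sum(y) <= C,  y binary,
           v in argmax { f'v : S v = 0, deletion bounds(y) }

is collapsed to a single MILP by LP duality: primal feasibility, dual
feasibility and the strong-duality equality of the inner growth LP are all
imposed as constraints, with big-M linearisation of the dual-variable x
knockout-binary products.  Reaction disabling is linked to gene binaries
through minimal cut sets and prime implicants of each GPR rule, which encodes
AND/OR logic exactly.  A multi-path local search (neighbourhood radius M,
k paths) iterates MILP solves around the best incumbent sets.

Every strategy the MILP proposes is re-simulated independently through
``knockout_genes`` + ``solve_fba`` before being reported, and greedily pruned
of genes that do not affect the outcome; the reported numbers therefore never
depend on the MILP's big-M fidelity.

``enumerate_knockouts_bruteforce`` is the exact reference: it scores every
knockout subset by the same two-step LP (inner growth optimum, then target
flux at that optimum under the configured tie-break).

``must_singles`` is a single-reaction flux-range classifier in the style of
the OptForce MUST sets: a reaction whose flux range under an overproduction
requirement is disjoint from its wild-type (e.g. 13C-constrained) range must
be up- or down-regulated in any overproducing strain.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from ._solver import OPTIMAL, solve_lp, solve_milp
from .fba import flux_variability, solve_fba
from .model import MetabolicModel, knockout_genes

__all__ = [
    "DeletionMatrix",
    "GdlsConfig",
    "KnockoutStrategy",
    "MustClassification",
    "build_deletion_matrix",
    "deletion_bounds",
    "gdls_search",
    "enumerate_knockouts_bruteforce",
    "must_singles",
]

log = logging.getLogger(__name__)

_TOL = 1e-9


@dataclass
class DeletionMatrix:
    """Gene-to-reaction deletion incidence for a candidate gene set.

    ``G[l, j] = 1`` iff knocking out gene ``l`` alone disables reaction ``j``.
    OR-protected (isozyme) reactions have no single disabling gene; their
    multi-gene knockout behaviour is carried by ``cut_sets`` (minimal gene
    sets that disable the reaction) and ``implicants`` (minimal gene sets
    whose presence keeps it alive).
    """

    genes: list[str]
    reactions: list[str]
    G: np.ndarray
    a: np.ndarray
    b: np.ndarray
    cut_sets: list[list[frozenset[str]]]
    implicants: list[list[frozenset[str]]]


@dataclass(frozen=True)
class GdlsConfig:
    """Search configuration for :func:`gdls_search`.

    ``max_knockouts`` is the knockout budget C; ``min_growth`` the growth
    floor accepted strategies must keep (default 0.05 /h); ``candidate_genes``
    restricts the search (e.g. to EMP/PPP/purine enzymes); ``neighborhood_size``
    and ``search_paths`` are the local-search radius M and path count k
    (``neighborhood_size=None`` means unbounded, i.e. one global MILP).
    """

    outer_objective_id: str
    inner_objective_id: str
    max_knockouts: int = 2
    min_growth: float = 0.05
    candidate_genes: frozenset[str] | None = None
    neighborhood_size: int | None = 1
    search_paths: int = 1
    tie_break: str = "optimistic"  # target flux reported at inner-optimal growth
    dual_bound: float = 1000.0
    max_iterations: int = 25

    def __post_init__(self):
        if self.max_knockouts < 0:
            raise ValueError("max_knockouts must be >= 0")
        if self.min_growth < 0:
            raise ValueError("min_growth must be >= 0")
        if self.tie_break not in {"optimistic", "pessimistic"}:
            raise ValueError("tie_break must be optimistic|pessimistic")


@dataclass(frozen=True)
class KnockoutStrategy:
    """A gene knockout set with its re-simulated phenotype."""

    knocked_genes: frozenset[str]
    predicted_target_flux: float
    predicted_growth: float
    provenance: str = "manual"
    tie_break: str = "optimistic"

    def sort_key(self):
        # quantise the target so LP-tolerance noise cannot reorder ties;
        # genuine ties fall back to fewer knockouts, then gene names
        return (
            -round(self.predicted_target_flux, 7),
            len(self.knocked_genes),
            sorted(self.knocked_genes),
        )


@dataclass
class MustClassification:
    """Flux-range classification of reactions under an overproduction floor."""

    classes: dict[str, str]
    wild_type_range: dict[str, tuple[float, float]]
    engineered_range: dict[str, tuple[float, float]]

    def reactions_in(self, cls: str) -> list[str]:
        return sorted(r for r, c in self.classes.items() if c == cls)


# ---------------------------------------------------------------------------
# deletion matrix
# ---------------------------------------------------------------------------

def build_deletion_matrix(
    model: MetabolicModel, candidate_genes: list[str] | None = None
) -> DeletionMatrix:
    """Gene/reaction deletion incidence plus exact cut-set/implicant encoding."""
    genes = sorted(set(candidate_genes) if candidate_genes is not None else set(model.genes))
    unknown = set(genes) - set(model.genes)
    if unknown:
        raise KeyError(f"unknown candidate genes: {sorted(unknown)}")
    rxn_ids = model.reaction_ids
    L, n = len(genes), len(rxn_ids)
    G = np.zeros((L, n), dtype=int)
    cut_sets: list[list[frozenset[str]]] = []
    implicants: list[list[frozenset[str]]] = []
    for j, r in enumerate(model.reactions):
        if r.gpr is None or r.gpr.is_empty:
            cut_sets.append([])
            implicants.append([frozenset()])
            continue
        cuts = r.gpr.minimal_cut_sets(candidates=genes)
        imps = r.gpr.prime_implicants(candidates=genes)
        cut_sets.append(cuts)
        implicants.append(imps)
        for c in cuts:
            if len(c) == 1:
                (g,) = c
                G[genes.index(g), j] = 1
    lb, ub = model.bounds_arrays()
    return DeletionMatrix(
        genes=genes, reactions=rxn_ids, G=G, a=lb, b=ub,
        cut_sets=cut_sets, implicants=implicants,
    )


def deletion_bounds(
    dm: DeletionMatrix, knocked: set[str] | frozenset[str]
) -> dict[str, tuple[float, float]]:
    """Per-reaction bounds implied by the deletion encoding for knockout set K.

    A reaction is disabled (bounds (0, 0)) iff one of its minimal cut sets is
    fully contained in K; this reproduces GPR knockout propagation exactly.
    """
    knocked = set(knocked)
    out: dict[str, tuple[float, float]] = {}
    for j, rid in enumerate(dm.reactions):
        disabled = any(c <= knocked for c in dm.cut_sets[j])
        out[rid] = (0.0, 0.0) if disabled else (float(dm.a[j]), float(dm.b[j]))
    return out


# ---------------------------------------------------------------------------
# strategy evaluation (shared by MILP path and brute force)
# ---------------------------------------------------------------------------

def evaluate_knockout(
    model: MetabolicModel,
    knocked: frozenset[str],
    outer_objective_id: str,
    inner_objective_id: str,
    tie_break: str = "optimistic",
) -> tuple[str, float, float]:
    """(status, growth, target) for one knockout set.

    Growth is the inner FBA optimum of the knocked model; the target flux is
    then re-optimised (max for optimistic, min for pessimistic) with growth
    fixed at that optimum.
    """
    km = knockout_genes(model, knocked)
    inner = solve_fba(km, inner_objective_id, "max")
    if not inner.optimal:
        return inner.status, math.nan, math.nan
    mu = inner.objective_value
    fixed = km.with_bounds({inner_objective_id: (mu - max(abs(mu), 1.0) * 1e-9, mu)})
    sense = "max" if tie_break == "optimistic" else "min"
    outer = solve_fba(fixed, outer_objective_id, sense)
    if not outer.optimal:
        return outer.status, mu, math.nan
    return OPTIMAL, float(mu), float(outer.objective_value)


def _make_strategy(model, knocked, config: GdlsConfig, provenance: str) -> KnockoutStrategy | None:
    status, mu, target = evaluate_knockout(
        model, knocked, config.outer_objective_id, config.inner_objective_id, config.tie_break
    )
    if status != OPTIMAL or mu < config.min_growth - _TOL:
        return None
    return KnockoutStrategy(
        knocked_genes=frozenset(knocked),
        predicted_target_flux=target,
        predicted_growth=mu,
        provenance=provenance,
        tie_break=config.tie_break,
    )


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def enumerate_knockouts_bruteforce(
    model: MetabolicModel,
    candidates: list[str],
    max_knockouts: int,
    config: GdlsConfig | None = None,
    subset_guard: int = 100_000,
) -> list[KnockoutStrategy]:
    """Exhaustively score every knockout subset of size <= C.

    Exact but combinatorial; refuses more than ``subset_guard`` subsets.
    Strategies failing the growth floor are dropped; the rest are sorted by
    target flux (descending), then set size, then gene names.
    """
    if config is None:
        raise ValueError("config (objectives, floor, tie-break) is required")
    candidates = sorted(set(candidates))
    n_subsets = sum(
        math.comb(len(candidates), k) for k in range(0, max_knockouts + 1)
    )
    if n_subsets > subset_guard:
        raise ValueError(
            f"{n_subsets} subsets exceed the enumeration guard ({subset_guard}); "
            "shrink the candidate set or budget"
        )
    out: list[KnockoutStrategy] = []
    for k in range(0, max_knockouts + 1):
        for combo in itertools.combinations(candidates, k):
            strat = _make_strategy(model, frozenset(combo), config, "bruteforce")
            if strat is not None:
                out.append(strat)
    out.sort(key=KnockoutStrategy.sort_key)
    return out


# ---------------------------------------------------------------------------
# GDLS MILP
# ---------------------------------------------------------------------------

class _GdlsMilp:
    """Single-level MILP encoding of the bi-level knockout problem."""

    def __init__(self, model: MetabolicModel, dm: DeletionMatrix, config: GdlsConfig):
        self.model = model
        self.dm = dm
        self.config = config
        self.idx = model.reaction_index()
        self.n = len(model.reactions)
        self.m = len(model.metabolites)
        self.L = len(dm.genes)
        # reactions that any candidate knockout can disable
        self.dis = [j for j in range(self.n) if dm.cut_sets[j]]
        self.nd = len(self.dis)
        self._build_static()

    def _build_static(self):
        model, dm, config = self.model, self.dm, self.config
        n, m, L, nd = self.n, self.m, self.L, self.nd
        dis_pos = {j: t for t, j in enumerate(self.dis)}
        U = float(config.dual_bound)
        a, b = dm.a.astype(float), dm.b.astype(float)

        # variable layout: v(n) y(L) z(nd) lam(m) mu(n) nu(n) p(nd) q(nd)
        self.off_v = 0
        self.off_y = n
        self.off_z = n + L
        self.off_lam = n + L + nd
        self.off_mu = self.off_lam + m
        self.off_nu = self.off_mu + n
        self.off_p = self.off_nu + n
        self.off_q = self.off_p + nd
        N = self.off_q + nd
        self.N = N

        lo = np.empty(N)
        hi = np.empty(N)
        lo[self.off_v : self.off_v + n] = np.minimum(a, 0.0)
        hi[self.off_v : self.off_v + n] = np.maximum(b, 0.0)
        for j in range(n):
            if j not in dis_pos:  # bounds apply directly when not deletable
                lo[self.off_v + j] = a[j]
                hi[self.off_v + j] = b[j]
        lo[self.off_y : self.off_y + L] = 0.0
        hi[self.off_y : self.off_y + L] = 1.0
        lo[self.off_z : self.off_z + nd] = 0.0
        hi[self.off_z : self.off_z + nd] = 1.0
        lo[self.off_lam : self.off_lam + m] = -np.inf
        hi[self.off_lam : self.off_lam + m] = np.inf
        lo[self.off_mu : self.off_mu + 2 * n + 2 * nd] = 0.0
        hi[self.off_mu : self.off_mu + 2 * n] = U
        hi[self.off_p : self.off_p + 2 * nd] = U
        self.bounds_lo, self.bounds_hi = lo, hi

        integrality = np.zeros(N)
        integrality[self.off_y : self.off_y + L] = 1
        integrality[self.off_z : self.off_z + nd] = 1
        self.integrality = integrality

        rows: list[dict[int, float]] = []
        rlo: list[float] = []
        rhi: list[float] = []

        def add(row: dict[int, float], lo_v: float, hi_v: float):
            rows.append(row)
            rlo.append(lo_v)
            rhi.append(hi_v)

        S = model.stoichiometric_matrix().tocoo()
        srows: dict[int, dict[int, float]] = {i: {} for i in range(m)}
        for i, j, val in zip(S.row, S.col, S.data):
            srows[i][self.off_v + j] = val
        for i in range(m):  # S v = 0
            add(srows[i], 0.0, 0.0)

        f = np.zeros(n)
        f[self.idx[config.inner_objective_id]] = 1.0
        g = np.zeros(n)
        g[self.idx[config.outer_objective_id]] = 1.0
        self.f, self.g = f, g

        # deletion window: a_j(1-z) <= v_j <= b_j(1-z)
        for t, j in enumerate(self.dis):
            add({self.off_v + j: 1.0, self.off_z + t: b[j]}, -np.inf, b[j])
            add({self.off_v + j: 1.0, self.off_z + t: a[j]}, a[j], np.inf)

        # GPR linking: cut sets force z on, implicants force z off
        gene_pos = {gid: l for l, gid in enumerate(dm.genes)}
        for t, j in enumerate(self.dis):
            for cut in dm.cut_sets[j]:
                row = {self.off_z + t: 1.0}
                for gid in cut:
                    row[self.off_y + gene_pos[gid]] = -1.0
                add(row, 1.0 - len(cut), np.inf)
            for imp in dm.implicants[j]:
                row = {self.off_z + t: 1.0}
                for gid in imp:
                    row[self.off_y + gene_pos[gid]] = -1.0
                add(row, -np.inf, 0.0)

        # knockout budget and growth floor
        add({self.off_y + l: 1.0 for l in range(L)}, -np.inf, float(config.max_knockouts))
        add({self.off_v + j: f[j] for j in np.nonzero(f)[0]}, float(config.min_growth), np.inf)

        # dual stationarity: S' lam + mu - nu = f
        Scsc = model.stoichiometric_matrix().tocsc()
        for j in range(n):
            row = {self.off_mu + j: 1.0, self.off_nu + j: -1.0}
            col = Scsc.getcol(j).tocoo()
            for i, val in zip(col.row, col.data):
                row[self.off_lam + i] = val
            add(row, f[j], f[j])

        # strong duality: f'v = sum_j b_j (mu_j - p_j) - a_j (nu_j - q_j)
        row = {self.off_v + self.idx[config.inner_objective_id]: 1.0}
        for j in range(n):
            row[self.off_mu + j] = row.get(self.off_mu + j, 0.0) - b[j]
            row[self.off_nu + j] = row.get(self.off_nu + j, 0.0) + a[j]
        for t, j in enumerate(self.dis):
            row[self.off_p + t] = b[j]
            row[self.off_q + t] = -a[j]
        add(row, 0.0, 0.0)

        # big-M linearisation of p = mu*z and q = nu*z
        for t, j in enumerate(self.dis):
            add({self.off_p + t: 1.0, self.off_mu + j: -1.0}, -np.inf, 0.0)
            add({self.off_p + t: 1.0, self.off_mu + j: -1.0, self.off_z + t: -U}, -U, np.inf)
            add({self.off_p + t: 1.0, self.off_z + t: -U}, -np.inf, 0.0)
            add({self.off_q + t: 1.0, self.off_nu + j: -1.0}, -np.inf, 0.0)
            add({self.off_q + t: 1.0, self.off_nu + j: -1.0, self.off_z + t: -U}, -U, np.inf)
            add({self.off_q + t: 1.0, self.off_z + t: -U}, -np.inf, 0.0)

        self.static_rows, self.static_lo, self.static_hi = rows, rlo, rhi

        c = np.zeros(N)
        c[self.off_v : self.off_v + n] = g
        self.c = c

    def solve(
        self,
        center: frozenset[str] | None = None,
        radius: int | None = None,
        excluded: list[frozenset[str]] = (),
        time_limit: float | None = 60.0,
    ) -> frozenset[str] | None:
        """Solve the MILP, optionally restricted to a Hamming neighbourhood of
        ``center`` and with no-good cuts excluding previously seen sets."""
        rows = list(self.static_rows)
        rlo = list(self.static_lo)
        rhi = list(self.static_hi)
        gene_pos = {gid: l for l, gid in enumerate(self.dm.genes)}
        if center is not None and radius is not None:
            row = {}
            base = 0.0
            for gid, l in gene_pos.items():
                if gid in center:
                    row[self.off_y + l] = -1.0
                    base += 1.0
                else:
                    row[self.off_y + l] = 1.0
            rows.append(row)
            rlo.append(-np.inf)
            rhi.append(float(radius) - base)
        for seen in excluded:
            row = {}
            base = 0.0
            for gid, l in gene_pos.items():
                if gid in seen:
                    row[self.off_y + l] = -1.0
                    base += 1.0
                else:
                    row[self.off_y + l] = 1.0
            rows.append(row)
            rlo.append(1.0 - base)
            rhi.append(np.inf)

        data, ri, ci = [], [], []
        for i, row in enumerate(rows):
            for j, val in row.items():
                ri.append(i)
                ci.append(j)
                data.append(val)
        A = sparse.csr_matrix((data, (ri, ci)), shape=(len(rows), self.N))
        res = solve_milp(
            self.c, A, np.array(rlo), np.array(rhi),
            self.bounds_lo, self.bounds_hi, self.integrality,
            sense="max", time_limit=time_limit,
        )
        if res.status != OPTIMAL:
            log.info("GDLS MILP status: %s", res.status)
            return None
        y = res.x[self.off_y : self.off_y + self.L]
        return frozenset(g for g, l in gene_pos.items() if y[l] > 0.5)


def _prune(model, knocked: frozenset[str], config: GdlsConfig) -> frozenset[str]:
    """Greedily drop genes whose removal leaves growth and target unchanged."""
    base = _make_strategy(model, knocked, config, "gdls")
    if base is None:
        return knocked
    current = set(knocked)
    for gid in sorted(knocked):
        if gid not in current:
            continue
        trial = frozenset(current - {gid})
        st = _make_strategy(model, trial, config, "gdls")
        if st is not None and (
            st.predicted_target_flux >= base.predicted_target_flux - 1e-7
        ):
            current.discard(gid)
            base = st
    return frozenset(current)


def gdls_search(model: MetabolicModel, config: GdlsConfig) -> list[KnockoutStrategy]:
    """Multi-path GDLS over gene-knockout sets.

    Returns the distinct locally optimal strategies found, each satisfying
    the knockout budget and the growth floor, sorted by predicted target flux
    (descending).  Returns an empty list with a logged diagnostic if the MILP
    is infeasible (e.g. the growth floor is unreachable).
    """
    wild = solve_fba(model, config.inner_objective_id, "max")
    if not wild.optimal or wild.objective_value < config.min_growth - _TOL:
        log.warning(
            "wild-type growth %s below floor %.3g; GDLS not started",
            getattr(wild, "objective_value", None), config.min_growth,
        )
        return []
    if config.max_knockouts == 0:
        st = _make_strategy(model, frozenset(), config, "gdls")
        return [st] if st is not None else []

    candidates = (
        sorted(config.candidate_genes) if config.candidate_genes is not None else model.genes
    )
    dm = build_deletion_matrix(model, candidates)
    milp = _GdlsMilp(model, dm, config)

    found: dict[frozenset[str], KnockoutStrategy] = {}

    def record(knocked: frozenset[str] | None) -> KnockoutStrategy | None:
        if knocked is None:
            return None
        knocked = _prune(model, knocked, config)
        if knocked in found:
            return found[knocked]
        st = _make_strategy(model, knocked, config, "gdls")
        if st is not None:
            found[knocked] = st
        return st

    if config.neighborhood_size is None:
        # unbounded neighbourhood: one global MILP, then no-good re-solves for
        # alternate optima / runners-up
        excluded: list[frozenset[str]] = []
        for _ in range(max(config.search_paths, 2)):
            raw = milp.solve(excluded=excluded)
            if raw is None:
                break
            record(raw)
            excluded.append(raw)
    else:
        paths: list[frozenset[str]] = [frozenset()]
        best_val = -math.inf
        for _ in range(config.max_iterations):
            proposals: list[KnockoutStrategy] = []
            for center in paths:
                excluded: list[frozenset[str]] = []
                for _k in range(config.search_paths):
                    raw = milp.solve(center=center, radius=config.neighborhood_size,
                                     excluded=excluded)
                    if raw is None:
                        break
                    excluded.append(raw)
                    st = record(raw)
                    if st is not None:
                        proposals.append(st)
            if not proposals:
                break
            proposals.sort(key=KnockoutStrategy.sort_key)
            top = proposals[0]
            if top.predicted_target_flux <= best_val + 1e-9:
                break
            best_val = top.predicted_target_flux
            paths = [p.knocked_genes for p in proposals[: config.search_paths]]

    out = sorted(found.values(), key=KnockoutStrategy.sort_key)
    if not out:
        log.warning("GDLS found no strategy satisfying the growth floor")
    return out


# ---------------------------------------------------------------------------
# MUST singles
# ---------------------------------------------------------------------------

def must_singles(
    model: MetabolicModel,
    wt_bounds: dict[str, tuple[float, float]],
    overproduction_floor: float,
    target_id: str | None = None,
    rxn_ids: list[str] | None = None,
    tol: float = 1e-6,
) -> MustClassification:
    """Classify reactions by wild-type vs overproduction flux-range disjunction.

    Wild-type ranges are FVA ranges under the measured (e.g. 13C-derived)
    bound table; engineered ranges are FVA ranges of the unconstrained model
    forced to synthesise at least ``overproduction_floor`` of the target.
    ``must_up``: engineered min above wild-type max; ``must_down``: engineered
    max below wild-type min; ``must_zero``: engineered range pinned to zero
    while the wild-type range excludes it.
    """
    target_id = target_id or model.objective_id
    unknown = set(wt_bounds) - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"bound table references unknown reactions: {sorted(unknown)}")
    rxn_ids = list(rxn_ids) if rxn_ids is not None else model.reaction_ids

    wt_model = model.with_bounds({rid: b for rid, b in wt_bounds.items()})
    probe = solve_fba(wt_model, target_id, "max")
    if not probe.optimal:
        raise ValueError("wild-type bound table makes the model infeasible")
    eng_max = solve_fba(model, target_id, "max")
    if not eng_max.optimal:
        raise ValueError(f"model is {eng_max.status}")
    if overproduction_floor > eng_max.objective_value + tol:
        raise ValueError(
            f"overproduction floor {overproduction_floor:g} exceeds the theoretical "
            f"maximum {eng_max.objective_value:g}"
        )
    eng_model = model.with_bounds(
        {target_id: (overproduction_floor, model.reaction(target_id).upper_bound)}
    )

    wt_rng = flux_variability(wt_model, rxn_ids, fraction_of_optimum=0.0)
    eng_rng = flux_variability(eng_model, rxn_ids, fraction_of_optimum=0.0)

    classes: dict[str, str] = {}
    for rid in rxn_ids:
        wlo, whi = wt_rng[rid]
        elo, ehi = eng_rng[rid]
        if abs(elo) <= tol and abs(ehi) <= tol and (wlo > tol or whi < -tol):
            classes[rid] = "must_zero"
        elif elo > whi + tol:
            classes[rid] = "must_up"
        elif ehi < wlo - tol:
            classes[rid] = "must_down"
        else:
            classes[rid] = "unclassified"
    return MustClassification(classes=classes, wild_type_range=wt_rng, engineered_range=eng_rng)
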