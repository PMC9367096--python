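# Methods

## Model representation and conventions

A model is a list of metabolites (rows of the stoichiometric matrix S), a
list of bounded reactions (columns), a gene list, and one objective reaction
with a sense.  Fluxes are in mmol/gDW/h; the biomass reaction flux is the
growth rate in h⁻¹.  Exchange reactions follow the boundary convention
``1 M →`` (exactly one metabolite, coefficient −1): negative flux is uptake,
positive is secretion.  A published "upper limit of the uptake rate" u
therefore becomes ``lower_bound = −u``; this is the only reading under which
uptake caps and negative mineral "lower limits" are mutually consistent, and
`fluxdesign.media.aerobic_minimal_medium` encodes it.  Freely exchanged
species get the conventional sentinel bounds (−1000, 1000); true infinities
are supported and serialized as ``"inf"``/``"-inf"``.

GPR rules are monotone boolean AND/OR trees over gene identifiers; an absent
rule always evaluates true.  Knocking out a gene set zeroes the bounds of
every reaction whose rule evaluates false.  Since the rules are monotone,
each rule has a unique set of minimal cut sets (gene sets whose joint loss
kills the reaction) and prime implicants (minimal gene sets whose presence
keeps it alive); both are computed by ascending-cardinality enumeration,
guarded at 16 genes per rule.  Ids are opaque, case-sensitive tokens.
Subunit stoichiometry beyond AND/OR is not representable.

I/O: SBML Level 3 + FBC v2 (bounds as constant parameters, gene-product
associations, one flux objective; kinetic laws, rules and events are
reported as unsupported, never silently dropped; conventional ``M_/R_/G_``
prefixes added on write and stripped on read), a canonical JSON dialect
(sorted ids and keys, hence bit-stable output), and a TSV pair
(`reactions.tsv` with columns reaction_id/equation/lower_bound/upper_bound/
gpr/subsystem, plus `metabolites.tsv`).  The TSV dialect does not carry
reaction display names; load∘write is the identity in every format on models
within each format's vocabulary.

## Flux balance analysis

FBA solves max cᵀ·v over {S·v = 0, v_min ≤ v ≤ v_max} with HiGHS
(scipy.optimize.linprog).  Infeasible/unbounded outcomes are reported as a
status, never raised.  Feasibility tolerance is 1e−9 and objective
comparisons in tests use 1e−6 relative; optimal flux *vectors* are
degenerate in general, so tests assert objective values only unless FVA
proves uniqueness.  FVA min/maxes each reaction subject to an optional
objective floor (fraction × optimum; fraction 0 drops the floor).  The
production envelope fixes growth on a uniform grid spanning [0, μ_max]
(default 20 points, both endpoints included) and min/maxes the target; its
upper boundary is piecewise-linear concave by parametric-LP theory, which
the tests verify by chord comparisons.  `theoretical_maxima` reports
(μ_max, target_max, molar yield at target_max) in one call; synthesis-rate
maxima can be quoted with growth left free or pinned at zero, so both modes
are exposed (``growth_fixed``), and they coincide on the fixture.

For intracellular targets (IMP is not in the secreted-metabolite set of
genome-scale *B. subtilis* models) a demand sink ``DM_<met>`` is added when
absent — the only way a "synthesis rate" has an LP meaning.

## GDLS

The bi-level knockout design (outer: max target flux g′v over binary
knockouts y with Σy ≤ C and a growth floor, default 0.05 h⁻¹; inner: max
growth f′v under deletion bounds) is converted to one MILP:

* primal feasibility of the inner LP with deletion binaries z_j zeroing
  bounds, linked to gene binaries exactly via cut-set (z forced on) and
  prime-implicant (z forced off) constraints — this matches the classic
  linear deletion form ``(1−y)′G_j a_j ≤ v_j ≤ (1−y)′G_j b_j`` where that
  form is exact (single-gene and pure-AND rules) and extends it correctly to
  OR-isozymes, which a single linear factor cannot express;
* dual feasibility (S′λ + μ − ν = f with μ, ν ≥ 0 bounded by a configurable
  dual bound, default 1000) and the strong-duality equality, with big-M
  linearization of the μ_j·z_j and ν_j·z_j products.

The MILP optimum is the *optimistic* bilevel value: among inner-optimal flux
states the target is maximized.  A pessimistic variant (min target at the
inner optimum) is also implemented; the optimistic one is the default
because a strategy table needs one number per strategy, and the choice is
flagged on every result.  Every MILP solution is re-simulated independently
(GPR knockout + FBA, then target re-optimization at the fixed growth
optimum) and greedily pruned of genes that do not change the outcome, so
reported numbers never depend on big-M fidelity; the dual bound is validated
by the brute-force equivalence suite.  Multi-path local search (radius M,
k paths, defaults M = 1, k = 1 as in the original local-search formulation;
``neighborhood_size=None`` gives one global solve) iterates MILP solves
around incumbents with no-good cuts for diversity.  Strategy ranking
quantizes the target flux at 1e−7 before sorting so LP-tolerance noise
cannot reorder ties; genuine ties prefer fewer knockouts.

`enumerate_knockouts_bruteforce` scores every subset (guarded at 1e5
subsets) with the identical two-step evaluation and is the exact reference.

## ROOM

Given a reference flux vector w, thresholds δ = 0.03 and ε = 0.001 (the
canonical ROOM values, with the symmetric window
w_i − δ|w_i| − ε ≤ v_i ≤ w_i + δ|w_i| + ε of the original formulation),
and a forced-zero set A, the MILP minimizes Σ y_i subject to steady state,
bounds, v_j = 0 on A, and the window constraints with the model's own
v_min/v_max as big-M (no artificial constants).  Reporting among the
typically non-unique ROOM optima is lexicographic: fix Σy at its minimum,
maximize growth, then min/max the target at that growth; conventions for
this reporting vary between implementations, so this one is documented and
deterministic.  The reference w can come from FBA, parsimonious FBA
(min Σ|v| at the fixed optimum via |v| auxiliaries — the default, because it
is reproducible and respects forced lower bounds), or a measured table.
`assess_strategy` sweeps a growth grid, solving ROOM with growth pinned and
min/maxing the target at the ROOM optimum; infeasible grid points become
NaN rather than aborting the curve.

## MUST singles

Wild-type flux ranges are FVA ranges under a measured bound table (¹³C-MFA
style); engineered ranges are FVA ranges with the target forced above an
overproduction floor.  Classification: must_up if the engineered minimum
exceeds the wild-type maximum, must_down symmetrically, must_zero if the
engineered range is pinned to zero while the wild-type range excludes it,
otherwise unclassified (tolerance 1e−6).  Only single reactions are
classified; MUST pairs are out of scope.

## The purine-core fixture

A 23-reaction, 17-metabolite, 12-gene carbon-skeleton network: glucose
uptake (−10 mmol/gDW/h), glycolysis (glcK, pgi, fbaA and a lumped lower
half), oxidative PPP (zwf AND ykgB, releasing CO₂), the full non-oxidative
PPP (tkt transketolases, ywjH transaldolase), PRS→PRPP, a lumped pur operon
(consuming PRPP plus g3p for the base carbons), IMP→inosine, degradation
(deoD OR pupG) to hypoxanthine plus ribose-1P, and the drm
phosphopentomutase returning ribose-1P to the PPP.  Growth is capped at
1 h⁻¹, standing in for unmodeled non-carbon requirements, so moderate
carbon waste does not move the growth optimum.

Two reactions carry small positive lower bounds: the transaldolase backflow
(0.3) and the drm turnover flux (0.5).  They model the obligatory
PPP→EMP shunt and nucleotide-turnover/degradation fluxes of the wild type,
and they are what makes the knockouts productive: zeroing a forced flux
releases carbon that plain reaction removal never could (an LP maximum can
only shrink when a feasible set shrinks).  Consequences that tests rely on:
knocking *drm* leaves μ_max unchanged while strictly raising the inosine
ceiling at mid growth; knocking *ywjH* strictly raises the IMP ceiling;
biomass and IMP compete along the envelope; and with the medium fully
closed the fixture is *infeasible* (status, not zero objective), because the
forced fluxes have no carbon source — the closed-medium-gives-zero property
is instead exhibited by the random toys, which have no forced bounds.

Deliberate simplifications relative to a genome-scale model: no cofactors
(ATP/NAD(P)H), no nitrogen/phosphate balancing, pseudo-carbon stoichiometry
chosen for exact hand arithmetic (round bounds, unit coefficients).  Passing
tests on the fixture therefore demonstrate algorithmic correctness —
oracle equivalence, geometry, knockout logic — not quantitative agreement
with any organism; genome-scale magnitudes are only reachable through the
optional external-model script.

The ¹³C-style bound table pins glycolysis high (GLK 8–9.5) and the
oxidative PPP low (ZWF 0.5–1.5), jointly feasible with the defaults, so
that a near-maximal IMP requirement forces ZWF far above its wild-type
range (must_up).

The random toy generator builds a fixed feasible backbone (substrate →
chain → biomass, plus a competing product branch) and layers seeded
unit-coefficient conversions with random GPRs on top (isozyme/complex
fractions configurable); every generated model validates, grows, and is
bit-reproducible per seed.

## Problem sizes and defaults

All shipped analyses are desk-scale: the fixture has 23 reactions; random
toys 13–14; oracle suites use 100 toys for FBA equivalence, 8 for GDLS
cross-checks, and 6 for exhaustive ROOM (ascending-cardinality enumeration,
cut off at 6 changed reactions).  The full test suite runs in well under a
minute on one CPU; `scripts/acceptance.py` in a few seconds.

## Known limitations

* No loopless/thermodynamic constraints, gap-filling, kinetics, MOMA, or
  regulatory-network reference states.
* The GDLS dual bound is a finite big-M; pathological models with huge dual
  multipliers could defeat it — mitigated (and detected) by mandatory
  re-simulation of every strategy.
* MILP solve times grow quickly with candidate-gene count; genome-scale GDLS
  should restrict candidates to the pathways of interest.
* The SBML subset ignores kinetic laws, rules, events and boundary species
  (with a warning); charge/formula survive, other annotations do not.
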