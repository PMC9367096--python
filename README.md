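# fluxdesign

Constraint-based metabolic flux analysis and in-silico knockout strain design
for overproduction of intracellular metabolites — built around the workflow
used to engineer purine-nucleoside (IMP/inosine) producers in *Bacillus
subtilis*, but applicable to any stoichiometric model.

## Who this is for

Metabolic engineers who want to go from a genome-scale (or toy) model to a
ranked list of gene-knockout strategies, with each strategy stress-tested for
its predicted effect on growth and product flux — entirely in silico, before
any strain is built.

## What it computes

Given a stoichiometric matrix S, flux bounds v_min ≤ v ≤ v_max and
gene–protein–reaction (GPR) boolean rules:

* **FBA** — maximize cᵀ·v subject to S·v = 0 and the bounds; the standard LP
  for growth or product synthesis rates (mmol/gDW/h; growth in h⁻¹), with
  flux-variability analysis (FVA), molar yields, and biomass-vs-product
  **production envelopes** (robustness curves).
* **GDLS** — genetic design through local search: the bi-level program
  "outer: max product flux over knockout sets y (Σy ≤ C); inner: the cell
  maximizes growth f′v under the deletion bounds (1−y)′G_j a_j ≤ v_j ≤
  (1−y)′G_j b_j" is collapsed into a single MILP by LP duality and explored
  by a multi-path local search.  OR-isozyme GPRs, which the linear deletion
  form cannot express, are encoded exactly through minimal cut sets.  An
  exhaustive enumeration oracle provides the exact reference on small
  instances.
* **ROOM** — regulatory on/off minimization: after a knockout (v_j = 0 for
  j ∈ A), find the flux state minimizing Σ y_i, the number of reactions
  leaving the window w_i ± (δ|w_i| + ε) around the wild-type reference flux
  w (defaults δ = 0.03, ε = 0.001), then report the growth and product-flux
  consequences.
* **MUST singles** — OptForce-style classification: reactions whose flux
  range under an overproduction requirement is disjoint from their wild-type
  (e.g. ¹³C-constrained) range *must* be up- or down-regulated in any
  producing strain.

Models are read and written as SBML Level 3 + FBC v2, a documented JSON
dialect, or TSV tables; media as YAML/TSV.  All LPs and MILPs are solved with
HiGHS via SciPy.

The package ships a deterministic **purine-core** toy network (glycolysis,
both pentose-phosphate branches, PRPP→IMP→inosine synthesis, nucleoside
degradation, and the two backflow nodes drm/ywjH) on which every stage is
hand-traceable, plus a seeded random-model generator for fuzzing against
oracles.

## Worked example

```sh
fluxdesign toy --name purine-core --out model.json
fluxdesign fba --model model.json --objective BIOMASS
fluxdesign gdls --model model.json --target DM_imp --max-knockouts 2
fluxdesign room --model model.json --knock-genes drm,ywjH --target DM_imp
```

or from Python:

```python
from fluxdesign import (GdlsConfig, RoomConfig, gdls_search, purine_core_model,
                        reactions_disabled_by, reference_flux, solve_fba,
                        solve_room, theoretical_maxima)

model = purine_core_model()
tm = theoretical_maxima(model, "BIOMASS", "DM_imp", "EX_glc")
print(tm.mu_max, tm.target_max, tm.yield_at_target_max)
# 1.0 6.4 0.64

cfg = GdlsConfig(outer_objective_id="DM_imp", inner_objective_id="BIOMASS",
                 max_knockouts=2, min_growth=0.05, neighborhood_size=None)
best = gdls_search(model, cfg)[0]
print(sorted(best.knocked_genes), round(best.predicted_target_flux, 3))
# ['drm', 'ywjH'] 5.967

w = reference_flux(model, "fba_parsimonious")
room = solve_room(model, RoomConfig(reference_flux=w,
                  forced_zero=frozenset(reactions_disabled_by(model, best.knocked_genes))),
                  target_id="DM_imp")
print(room.n_changed, round(room.growth, 3), round(room.target_flux, 3))
# 15 1.0 0.296
```

Reading the numbers: the wild-type toy cell grows at 1.0 h⁻¹ and could
synthesize at most 6.4 mmol/gDW/h of IMP (0.64 mol per mol glucose) if it
stopped growing.  GDLS picks the knockout of *drm* (phosphopentomutase, the
purine-degradation backflow node) plus *ywjH* (transaldolase, the PPP→EMP
backflow node) as the best two-gene strategy: it raises the IMP ceiling to
5.97 mmol/gDW/h without touching the growth optimum.  ROOM then predicts
what the mutant will actually do: rerouting 15 reactions, keeping full
growth, and carrying 0.296 mmol/gDW/h of IMP flux — the minimal-adjustment
flux state rather than the theoretical ceiling.

The full pipeline (load → maxima → envelope → GDLS → ROOM → MUST) runs from
one YAML config: `fluxdesign pipeline --config config.yaml`.

To apply the workflow to the published genome-scale *B. subtilis* model
(iBsu1103V2, downloaded separately), see `scripts/external_model.py --help`;
`fluxdesign.media.aerobic_minimal_medium` builds the corresponding glucose
minimal medium (uptake caps 9.5/10.9/15.1 mmol/gDW/h for glucose/O₂/CO₂).

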