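#!/usr/bin/env python
"""Optional: run the design pipeline on a user-supplied genome-scale model.

This package's test surface is self-contained; this script is the documented
path for reproducing the genome-scale *B. subtilis* numbers on the published
iBsu1103V2 model, which must be downloaded separately (it is not shipped and
is never fetched automatically).

Usage:
    python scripts/external_model.py --sbml iBsu1103V2.xml \
        --glucose EX_cpd00027_e --o2 EX_cpd00007_e --co2 EX_cpd00011_e \
        --phosphate EX_cpd00009_e --sulfate EX_cpd00048_e --ammonia EX_cpd00013_e \
        --free EX_cpd00001_e,EX_cpd00067_e,... \
        --biomass bio00006 --target DM_imp --imp-metabolite cpd00126_c \
        --out results/external

The medium applied is the aerobic glucose minimal medium (uptake caps 9.5 /
10.9 / 15.1 mmol/gDW/h for glucose / O2 / CO2, 5 for minerals, free ions
unbounded, everything else closed).  Exchange/metabolite identifiers differ
between model distributions, so they must be given explicitly.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from fluxdesign import io as fio
from fluxdesign.design import GdlsConfig, gdls_search
from fluxdesign.fba import theoretical_maxima
from fluxdesign.media import aerobic_minimal_medium
from fluxdesign.model import apply_medium, reactions_disabled_by
from fluxdesign.pipeline import _ensure_demand
from fluxdesign.room import RoomConfig, reference_flux, solve_room


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sbml", required=True, type=Path)
    parser.add_argument("--glucose", required=True)
    parser.add_argument("--o2", required=True)
    parser.add_argument("--co2", required=True)
    parser.add_argument("--phosphate", required=True)
    parser.add_argument("--sulfate", required=True)
    parser.add_argument("--ammonia", required=True)
    parser.add_argument("--free", default="", help="comma-separated free-ion exchanges")
    parser.add_argument("--biomass", required=True)
    parser.add_argument("--target", default="DM_imp")
    parser.add_argument("--candidates", default="",
                        help="comma-separated candidate genes (e.g. EMP/PPP/purine)")
    parser.add_argument("--max-knockouts", type=int, default=2)
    parser.add_argument("--min-growth", type=float, default=0.05)
    parser.add_argument("--out", required=True, type=Path)
    args = parser.parse_args()

    model = fio.load_model(args.sbml, "sbml")
    print("model summary:", fio.model_summary(model))
    medium = aerobic_minimal_medium(
        args.glucose, args.o2, args.co2, args.phosphate, args.sulfate, args.ammonia,
        free_ion_exchanges=[x for x in args.free.split(",") if x],
    )
    model = apply_medium(model, medium)
    model = _ensure_demand(model, args.target)

    report: dict = {}
    tm = theoretical_maxima(model, args.biomass, args.target, args.glucose)
    report["maxima"] = {
        "mu_max": tm.mu_max,
        "target_max": tm.target_max,
        "yield_mol_per_mol": tm.yield_at_target_max,
    }
    print("maxima:", report["maxima"])

    cfg = GdlsConfig(
        outer_objective_id=args.target,
        inner_objective_id=args.biomass,
        max_knockouts=args.max_knockouts,
        min_growth=args.min_growth,
        candidate_genes=frozenset(args.candidates.split(",")) if args.candidates else None,
        neighborhood_size=None,
        search_paths=3,
    )
    strategies = gdls_search(model, cfg)
    report["strategies"] = [
        {"genes": sorted(s.knocked_genes), "target_flux": s.predicted_target_flux,
         "growth": s.predicted_growth}
        for s in strategies
    ]
    print("strategies:", report["strategies"])

    w = reference_flux(model, "fba_parsimonious")
    report["room"] = []
    for s in strategies:
        res = solve_room(
            model,
            RoomConfig(
                reference_flux=w,
                forced_zero=frozenset(reactions_disabled_by(model, s.knocked_genes)),
            ),
            growth_id=args.biomass,
            target_id=args.target,
        )
        report["room"].append(
            {"genes": sorted(s.knocked_genes), "status": res.status,
             "n_changed": res.n_changed, "growth": res.growth,
             "target_flux": res.target_flux}
        )
        print("room:", report["room"][-1])

    args.out.mkdir(parents=True, exist_ok=True)
    with open(args.out / "external_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)


if __name__ == "__main__":
    main()
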