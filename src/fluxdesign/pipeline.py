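"""End-to-end strain-design pipeline.

Runs, in order: model load + medium application, theoretical maxima,
production envelope, GDLS knockout search, ROOM assessment of each returned
strategy, and (when a measured bound table is supplied) MUST classification.
Writes a machine-readable JSON report plus TSV tables; identical config and
seed give identical outputs (the timestamp is isolated in one field).
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as fio
from .design import GdlsConfig, gdls_search, must_singles
from .fba import production_envelope, theoretical_maxima
from .model import MetabolicModel, apply_medium, reactions_disabled_by
from .room import RoomConfig, reference_flux, solve_room

__all__ = ["PipelineConfig", "run_design_pipeline", "load_pipeline_config"]

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Run configuration for :func:`run_design_pipeline`."""

    model_path: str
    output_dir: str
    model_format: str | None = None
    medium_path: str | None = None
    biomass_id: str | None = None
    target_id: str = "DM_imp"
    substrate_id: str | None = None
    bounds_table_path: str | None = None
    envelope_points: int = 20
    max_knockouts: int = 2
    min_growth: float = 0.05
    candidate_genes: list[str] | None = None
    neighborhood_size: int | None = 1
    search_paths: int = 1
    room_delta: float = 0.03
    room_epsilon: float = 0.001
    must_floor_fraction: float = 0.9
    seed: int = 0


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    version = data.pop("config_version", 1)
    if version != 1:
        raise ValueError(f"unsupported config_version {version}")
    return PipelineConfig(**data)


def _ensure_demand(model: MetabolicModel, target_id: str) -> MetabolicModel:
    """Add a demand sink for an intracellular target when absent.

    A target like IMP is not secreted by genome-scale models; a sink reaction
    ``DM_<met>`` gives its synthesis rate an LP meaning.
    """
    if target_id in set(model.reaction_ids):
        return model
    met = target_id[3:] if target_id.startswith("DM_") else None
    if met is None or met not in {m.id for m in model.metabolites}:
        raise KeyError(f"target reaction {target_id!r} not in model")
    from .model import Reaction

    new = model.copy()
    new.reactions = list(new.reactions) + [
        Reaction(id=target_id, name=f"{met} demand", stoichiometry={met: -1.0},
                 lower_bound=0.0, upper_bound=1000.0)
    ]
    log.info("added demand sink %s for metabolite %s", target_id, met)
    return new


def run_design_pipeline(config: PipelineConfig) -> dict:
    """Execute the design pipeline; returns the report dict (also written to
    ``<output_dir>/report.json`` with companion TSV tables)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "generated_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": asdict(config),
    }

    stage = "load_model"
    try:
        model = fio.load_model(config.model_path, config.model_format)
        if config.medium_path:
            model = apply_medium(model, fio.read_medium(config.medium_path))
        biomass_id = config.biomass_id or model.objective_id
        model = _ensure_demand(model, config.target_id)
        substrate_id = config.substrate_id or _guess_substrate(model)
        report["model"] = fio.model_summary(model)
        log.info("model loaded: %s", report["model"])

        stage = "theoretical_maxima"
        tm = theoretical_maxima(model, biomass_id, config.target_id, substrate_id)
        report["maxima"] = {
            "mu_max": tm.mu_max,
            "target_max": tm.target_max,
            "yield_mol_per_mol": tm.yield_at_target_max,
        }
        log.info("maxima: %s", report["maxima"])

        stage = "production_envelope"
        env = production_envelope(model, biomass_id, config.target_id, config.envelope_points)
        report["envelope"] = {
            "growth": env.growth_grid,
            "min_target": env.min_target,
            "max_target": env.max_target,
        }
        pd.DataFrame(
            {"growth": env.growth_grid, "min_target": env.min_target,
             "max_target": env.max_target}
        ).to_csv(out / "envelope.tsv", sep="\t", index=False)

        stage = "gdls_search"
        gcfg = GdlsConfig(
            outer_objective_id=config.target_id,
            inner_objective_id=biomass_id,
            max_knockouts=config.max_knockouts,
            min_growth=config.min_growth,
            candidate_genes=frozenset(config.candidate_genes)
            if config.candidate_genes
            else None,
            neighborhood_size=config.neighborhood_size,
            search_paths=config.search_paths,
        )
        strategies = gdls_search(model, gcfg)
        report["strategies"] = [
            {
                "genes": sorted(s.knocked_genes),
                "reactions_disabled": sorted(reactions_disabled_by(model, s.knocked_genes)),
                "target_flux": s.predicted_target_flux,
                "growth": s.predicted_growth,
                "provenance": s.provenance,
                "tie_break": s.tie_break,
            }
            for s in strategies
        ]
        pd.DataFrame(
            [
                {
                    "strategy": i + 1,
                    "genes": ",".join(sorted(s.knocked_genes)),
                    "reactions_disabled": ",".join(
                        sorted(reactions_disabled_by(model, s.knocked_genes))
                    ),
                    "target_flux": s.predicted_target_flux,
                    "growth": s.predicted_growth,
                }
                for i, s in enumerate(strategies)
            ]
        ).to_csv(out / "strategies.tsv", sep="\t", index=False)
        log.info("GDLS returned %d strategies", len(strategies))

        stage = "room_assessment"
        wref = reference_flux(model, "fba_parsimonious")
        room_reports = []
        for s in strategies:
            forced = frozenset(reactions_disabled_by(model, s.knocked_genes))
            rres = solve_room(
                model,
                RoomConfig(
                    reference_flux=wref,
                    delta=config.room_delta,
                    epsilon=config.room_epsilon,
                    forced_zero=forced,
                ),
                growth_id=biomass_id,
                target_id=config.target_id,
            )
            room_reports.append(
                {
                    "genes": sorted(s.knocked_genes),
                    "status": rres.status,
                    "n_changed": rres.n_changed,
                    "growth": rres.growth,
                    "target_flux": rres.target_flux,
                    "target_range": list(rres.target_range) if rres.target_range else None,
                }
            )
            log.info("ROOM %s: %s", sorted(s.knocked_genes), room_reports[-1])
        report["room"] = room_reports
        report["room_reference"] = {
            "growth": wref.get(biomass_id), "target_flux": wref.get(config.target_id)
        }

        if config.bounds_table_path:
            stage = "must_singles"
            table = fio.read_bounds_table(config.bounds_table_path)
            floor = config.must_floor_fraction * tm.target_max
            mc = must_singles(model, table, floor, target_id=config.target_id,
                              rxn_ids=sorted(table))
            report["must"] = {
                "floor": floor,
                "classes": mc.classes,
                "must_up": mc.reactions_in("must_up"),
                "must_down": mc.reactions_in("must_down"),
                "must_zero": mc.reactions_in("must_zero"),
            }
    except Exception:
        log.exception("pipeline stage %r failed", stage)
        report["failed_stage"] = stage
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        raise

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def _guess_substrate(model: MetabolicModel) -> str:
    """The exchange with the most negative lower bound (the carbon source)."""
    candidates = [r for r in model.exchanges if r.lower_bound < 0]
    if not candidates:
        raise ValueError("no open uptake exchange found; specify substrate_id")
    return min(candidates, key=lambda r: r.lower_bound).id
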