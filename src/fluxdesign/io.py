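"""Model, medium and bound-table I/O.

Supported model formats
-----------------------
``json``
    The package's own dialect (schema version 1): ``{"id", "version",
    "objective": {"reaction", "sense"}, "genes": [...], "metabolites": [...],
    "reactions": [...]}`` with infinite bounds encoded as the strings
    ``"inf"`` / ``"-inf"``.  Output is canonical (sorted ids, sorted keys) and
    therefore bit-stable for a fixed model.
``tsv``
    A directory holding ``reactions.tsv`` (columns: reaction_id, equation,
    lower_bound, upper_bound, gpr, subsystem) and ``metabolites.tsv``
    (metabolite_id, name, compartment, formula, charge).  The objective is
    carried in ``#`` header comments.  Reaction display names are not stored
    in this dialect.
``sbml``
    SBML Level 3 + FBC v2, the subset used by constraint-based models: FBC
    flux bounds and gene-product associations, no kinetic laws.  Unsupported
    constructs encountered on read are reported, never silently dropped.
    Conventional ``M_``/``R_``/``G_`` id prefixes are added on write and
    stripped on read.

Media are read from YAML (``default_closed`` plus an ``exchanges`` map) or
TSV (exchange_id, lower_bound, upper_bound); reaction bound tables (e.g.
13C-derived flux windows) from TSV (reaction_id, lower_bound, upper_bound).
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path

import pandas as pd
import yaml

from .gpr import parse_gpr
from .model import (
    MediumSpec,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
)

__all__ = [
    "load_model",
    "write_model",
    "read_medium",
    "read_bounds_table",
    "write_bounds_table",
    "model_summary",
]

JSON_SCHEMA_VERSION = 1


def _enc_bound(x: float):
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return float(x)


def _dec_bound(x) -> float:
    if isinstance(x, str):
        return float(x)
    return float(x)


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_json_dict(model: MetabolicModel) -> dict:
    d = model.to_canonical_dict()
    d["version"] = JSON_SCHEMA_VERSION
    return d


def _model_from_json_dict(d: dict) -> MetabolicModel:
    mets = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", "c"),
            formula=m.get("formula"),
            charge=m.get("charge"),
        )
        for m in d["metabolites"]
    ]
    rxns = [
        Reaction(
            id=r["id"],
            name=r.get("name", ""),
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=_dec_bound(r["lower_bound"]),
            upper_bound=_dec_bound(r["upper_bound"]),
            gpr=parse_gpr(r["gpr"]) if r.get("gpr") else None,
            subsystem=r.get("subsystem"),
        )
        for r in d["reactions"]
    ]
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=list(d["genes"]),
        objective_id=d["objective"]["reaction"],
        objective_sense=d["objective"]["sense"],
        id=d.get("id", "model"),
    )


# ---------------------------------------------------------------------------
# TSV pair
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "-->", "<--")


def format_equation(stoichiometry: dict[str, float]) -> str:
    """Canonical parseable equation string: ``1 a + 2 b <=> 1 c``."""
    subs = [(m, -c) for m, c in sorted(stoichiometry.items()) if c < 0]
    prods = [(m, c) for m, c in sorted(stoichiometry.items()) if c > 0]

    def side(terms):
        return " + ".join(f"{c:g} {m}" for m, c in terms)

    return f"{side(subs)} <=> {side(prods)}".strip()


def parse_equation(text: str) -> dict[str, float]:
    for arrow in _ARROWS:
        if arrow in text:
            left, right = text.split(arrow, 1)
            break
    else:
        raise ValueError(f"no reaction arrow in equation {text!r}")
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float):
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 2:
                coeff, met = float(parts[0]), parts[1]
            elif len(parts) == 1:
                coeff, met = 1.0, parts[0]
            else:
                raise ValueError(f"malformed equation term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(left, -1.0)
    add_side(right, +1.0)
    return stoich


def _write_tsv(model: MetabolicModel, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    d = model.to_canonical_dict()
    rxn_rows = [
        {
            "reaction_id": r["id"],
            "equation": format_equation(r["stoichiometry"]),
            "lower_bound": r["lower_bound"],
            "upper_bound": r["upper_bound"],
            "gpr": r["gpr"],
            "subsystem": r["subsystem"] or "",
        }
        for r in d["reactions"]
    ]
    header = (
        f"# model_id={d['id']}\n"
        f"# objective={d['objective']['reaction']}\n"
        f"# objective_sense={d['objective']['sense']}\n"
    )
    rxn_df = pd.DataFrame(rxn_rows)
    with open(path / "reactions.tsv", "w", encoding="utf-8") as fh:
        fh.write(header)
        rxn_df.to_csv(fh, sep="\t", index=False)
    met_rows = [
        {
            "metabolite_id": m["id"],
            "name": m["name"],
            "compartment": m["compartment"],
            "formula": m["formula"] or "",
            "charge": "" if m["charge"] is None else m["charge"],
        }
        for m in d["metabolites"]
    ]
    pd.DataFrame(met_rows).to_csv(path / "metabolites.tsv", sep="\t", index=False)


def _read_tsv(path: Path) -> MetabolicModel:
    meta: dict[str, str] = {}
    with open(path / "reactions.tsv", encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            if "=" in line:
                key, val = line[1:].split("=", 1)
                meta[key.strip()] = val.strip()
        else:
            break
    from io import StringIO

    rxn_df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t", dtype=str)
    met_df = pd.read_csv(path / "metabolites.tsv", sep="\t", dtype=str)
    mets = [
        Metabolite(
            id=row["metabolite_id"],
            name="" if pd.isna(row["name"]) else row["name"],
            compartment=row["compartment"],
            formula=None if pd.isna(row.get("formula")) or row.get("formula") == "" else row["formula"],
            charge=None
            if pd.isna(row.get("charge")) or row.get("charge") == ""
            else int(float(row["charge"])),
        )
        for _, row in met_df.iterrows()
    ]
    rxns = []
    genes: set[str] = set()
    for _, row in rxn_df.iterrows():
        gpr_text = "" if pd.isna(row["gpr"]) else row["gpr"]
        gpr = parse_gpr(gpr_text) if gpr_text else None
        if gpr is not None:
            genes |= gpr.genes
        rxns.append(
            Reaction(
                id=row["reaction_id"],
                stoichiometry=parse_equation(row["equation"]),
                lower_bound=float(row["lower_bound"]),
                upper_bound=float(row["upper_bound"]),
                gpr=gpr,
                subsystem=None if pd.isna(row["subsystem"]) or row["subsystem"] == "" else row["subsystem"],
            )
        )
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=sorted(genes),
        objective_id=meta.get("objective", rxns[-1].id if rxns else ""),
        objective_sense=meta.get("objective_sense", "max"),
        id=meta.get("model_id", path.name),
    )


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC v2 subset
# ---------------------------------------------------------------------------

_SID_OK = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _sid(prefix: str, raw: str) -> str:
    s = re.sub(r"[^A-Za-z0-9_]", "__", raw)
    if not _SID_OK.match(s):
        s = "x" + s
    return prefix + s


def _strip(prefix: str, sid: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sid("", model.id))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for comp in sorted({m.compartment for m in model.metabolites}):
        c = sm.createCompartment()
        c.setId(_sid("", comp))
        c.setConstant(True)

    for m in sorted(model.metabolites, key=lambda m: m.id):
        s = sm.createSpecies()
        s.setId(_sid("M_", m.id))
        s.setName(m.name)
        s.setCompartment(_sid("", m.compartment))
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        splug = s.getPlugin("fbc")
        if m.charge is not None:
            splug.setCharge(int(m.charge))
        if m.formula:
            splug.setChemicalFormula(m.formula)

    for g in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(_sid("G_", g))
        gp.setLabel(g)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for r in sorted(model.reactions, key=lambda r: r.id):
        sr = sm.createReaction()
        sr.setId(_sid("R_", r.id))
        sr.setName(r.name)
        sr.setReversible(r.lower_bound < 0)
        sr.setFast(False)
        for met, coeff in sorted(r.stoichiometry.items()):
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(_sid("M_", met))
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        if r.subsystem:
            sr.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">'
                f"<p>SUBSYSTEM: {r.subsystem}</p></body>"
            )
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(float(r.lower_bound)))
        rplug.setUpperFluxBound(bound_param(float(r.upper_bound)))
        if r.gpr is not None and not r.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            infix = _gpr_to_infix(r.gpr)
            assoc = libsbml.FbcAssociation.parseFbcInfixAssociation(infix, mplug)
            if assoc is None:
                raise ValueError(f"cannot encode GPR for reaction {r.id!r}: {infix!r}")
            gpa.setAssociation(assoc)

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize" if model.objective_sense == "max" else "minimize")
    fo = obj.createFluxObjective()
    fo.setReaction(_sid("R_", model.objective_id))
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def _gpr_to_infix(expr) -> str:
    # gene *labels* are used in the infix so the parser binds to the declared
    # gene products rather than inventing new ones
    if expr.op == "gene":
        return expr.gene
    sep = f" {expr.op} "
    return "(" + sep.join(_gpr_to_infix(c) for c in expr.children) + ")"


def _assoc_to_gpr_text(assoc, label_by_id: dict[str, str]) -> str:
    import libsbml

    if isinstance(assoc, libsbml.GeneProductRef):
        gid = assoc.getGeneProduct()
        return label_by_id.get(gid, _strip("G_", gid))
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_assoc_to_gpr_text(assoc.getAssociation(i), label_by_id)
                 for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_assoc_to_gpr_text(assoc.getAssociation(i), label_by_id)
                 for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(parts) + ")"
    raise ValueError(f"unsupported gene association node {type(assoc).__name__}")


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise ModelValidationError([f"SBML read error: {m.strip()}" for m in msgs])
    sm = doc.getModel()
    if sm is None:
        raise ModelValidationError(["SBML file contains no model"])
    unsupported: list[str] = []
    if sm.getNumRules() or sm.getNumEvents() or sm.getNumConstraints():
        unsupported.append("rules/events/constraints are not supported")
    mplug = sm.getPlugin("fbc")
    if mplug is None:
        raise ModelValidationError(["SBML model has no FBC package information"])

    mets = []
    for i in range(sm.getNumSpecies()):
        s = sm.getSpecies(i)
        if s.getBoundaryCondition():
            # boundary species are outside the balanced system; skip their rows
            continue
        splug = s.getPlugin("fbc")
        mets.append(
            Metabolite(
                id=_strip("M_", s.getId()),
                name=s.getName() or "",
                compartment=s.getCompartment() or "c",
                formula=(splug.getChemicalFormula() or None)
                if splug is not None and splug.isSetChemicalFormula()
                else None,
                charge=splug.getCharge()
                if splug is not None and splug.isSetCharge()
                else None,
            )
        )
    met_ids = {m.id for m in mets}

    label_by_id = {}
    for i in range(mplug.getNumGeneProducts()):
        gp = mplug.getGeneProduct(i)
        label_by_id[gp.getId()] = gp.getLabel() or _strip("G_", gp.getId())

    def param_value(pid: str) -> float:
        p = sm.getParameter(pid)
        if p is None:
            raise ModelValidationError([f"flux bound parameter {pid!r} missing"])
        return float(p.getValue())

    rxns = []
    genes: set[str] = set()
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        if sr.isSetKineticLaw():
            unsupported.append(f"kinetic law on reaction {sr.getId()!r} ignored")
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = _strip("M_", ref.getSpecies())
            if mid in met_ids:
                stoich[mid] = stoich.get(mid, 0.0) - float(ref.getStoichiometry())
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = _strip("M_", ref.getSpecies())
            if mid in met_ids:
                stoich[mid] = stoich.get(mid, 0.0) + float(ref.getStoichiometry())
        subsystem = None
        if sr.isSetNotes():
            match = re.search(r"SUBSYSTEM:\s*([^<\n]+)", sr.getNotesString())
            if match:
                subsystem = match.group(1).strip()
        rplug = sr.getPlugin("fbc")
        lb = param_value(rplug.getLowerFluxBound())
        ub = param_value(rplug.getUpperFluxBound())
        gpr = None
        if rplug.isSetGeneProductAssociation():
            text = _assoc_to_gpr_text(
                rplug.getGeneProductAssociation().getAssociation(), label_by_id
            )
            gpr = parse_gpr(text)
            genes |= gpr.genes
        rxns.append(
            Reaction(
                id=_strip("R_", sr.getId()),
                name=sr.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                subsystem=subsystem,
            )
        )

    objective_id = rxns[0].id if rxns else ""
    sense = "max"
    obj = mplug.getActiveObjective() or (
        mplug.getObjective(0) if mplug.getNumObjectives() else None
    )
    if obj is not None and obj.getNumFluxObjectives() > 0:
        objective_id = _strip("R_", obj.getFluxObjective(0).getReaction())
        sense = "max" if obj.getType() == "maximize" else "min"

    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=sorted(genes),
        objective_id=objective_id,
        objective_sense=sense,
        id=_strip("", sm.getId() or path.stem),
    )
    if unsupported:
        import warnings

        warnings.warn("unsupported SBML constructs: " + "; ".join(unsupported))
    return model


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load and validate a model from ``json``, ``tsv`` or ``sbml``.

    The format is inferred from the path when not given (directories are TSV
    pairs, ``.json`` is JSON, ``.xml``/``.sbml`` is SBML).
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "tsv"
        elif path.suffix == ".json":
            format = "json"
        elif path.suffix in {".xml", ".sbml"}:
            format = "sbml"
        else:
            raise ValueError(f"cannot infer model format from {path}")
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            model = _model_from_json_dict(json.load(fh))
    elif format == "tsv":
        model = _read_tsv(path)
    elif format == "sbml":
        model = _read_sbml(path)
    else:
        raise ValueError(f"unknown model format {format!r}")
    model.validate()
    return model


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write a validated model; output is deterministic (sorted ids)."""
    model.validate()
    path = Path(path)
    if format is None:
        if path.suffix == ".json":
            format = "json"
        elif path.suffix in {".xml", ".sbml"}:
            format = "sbml"
        else:
            format = "tsv"
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(model_to_json_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif format == "tsv":
        _write_tsv(model, path)
    elif format == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


def read_medium(path: str | Path) -> MediumSpec:
    """Read a medium from YAML (``default_closed`` + ``exchanges``) or TSV."""
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        bounds = {
            rid: (float(v[0]), float(v[1])) for rid, v in data.get("exchanges", {}).items()
        }
        return MediumSpec(bounds=bounds, default_closed=bool(data.get("default_closed", True)))
    df = pd.read_csv(path, sep="\t")
    bounds = {
        str(row.iloc[0]): (float(row.iloc[1]), float(row.iloc[2])) for _, row in df.iterrows()
    }
    return MediumSpec(bounds=bounds, default_closed=True)


def read_bounds_table(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a reaction bound table (TSV: reaction_id, lower_bound, upper_bound)."""
    df = pd.read_csv(path, sep="\t")
    return {str(r.iloc[0]): (float(r.iloc[1]), float(r.iloc[2])) for _, r in df.iterrows()}


def write_bounds_table(bounds: dict[str, tuple[float, float]], path: str | Path) -> None:
    rows = [
        {"reaction_id": rid, "lower_bound": lb, "upper_bound": ub}
        for rid, (lb, ub) in sorted(bounds.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def model_summary(model: MetabolicModel) -> dict[str, int]:
    """Counts for comparison against published model property tables."""
    return {
        "metabolites": len(model.metabolites),
        "reactions": len(model.reactions),
        "genes": len(model.genes),
        "exchanges": len(model.exchanges),
    }
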