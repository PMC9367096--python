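"""Model domain types, medium application, knockout propagation, and I/O."""

import itertools
import json
import math
from pathlib import Path

import pytest

from conftest import make_toy
from fluxdesign import io as fio
from fluxdesign.fba import solve_fba
from fluxdesign.gpr import parse_gpr
from fluxdesign.media import aerobic_minimal_medium
from fluxdesign.model import (
    MediumSpec,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    apply_medium,
    knockout_genes,
    knockout_reactions,
)

DATA = Path(__file__).parent / "data"


def tiny_model(**overrides):
    kwargs = dict(
        metabolites=[Metabolite("a", compartment="e"), Metabolite("b")],
        reactions=[
            Reaction("EX_a", {"a": -1}, -10, 1000),
            Reaction("T", {"a": -1, "b": 1}, 0, 1000, gpr=parse_gpr("g1")),
            Reaction("DM_b", {"b": -1}, 0, 1000),
        ],
        genes=["g1"],
        objective_id="DM_b",
    )
    kwargs.update(overrides)
    return MetabolicModel(**kwargs)


class TestValidation:
    def test_valid_model_passes(self):
        tiny_model().validate()

    @pytest.mark.parametrize(
        "overrides,fragment",
        [
            (dict(objective_id="nope"), "objective"),
            (
                dict(reactions=[Reaction("R", {"missing": 1})], objective_id="R"),
                "unknown metabolite",
            ),
            (
                dict(reactions=[Reaction("R", {"a": 1}, 5, -5)], objective_id="R"),
                "lower_bound",
            ),
            (
                dict(
                    reactions=[
                        Reaction("R", {"a": 1}),
                        Reaction("R", {"b": 1}),
                    ],
                    objective_id="R",
                ),
                "duplicate reaction",
            ),
            (
                dict(
                    reactions=[Reaction("R", {"a": 1}, gpr=parse_gpr("gX"))],
                    objective_id="R",
                ),
                "unlisted genes",
            ),
        ],
    )
    def test_problems_are_listed(self, overrides, fragment):
        with pytest.raises(ModelValidationError) as exc:
            tiny_model(**overrides).validate()
        assert any(fragment in p for p in exc.value.problems)

    def test_exchange_convention(self):
        assert Reaction("EX", {"a": -1}).is_exchange
        assert not Reaction("R", {"a": -1, "b": 1}).is_exchange
        assert not Reaction("R", {"a": 1}).is_exchange


class TestMedium:
    def test_default_medium_opens_glucose_only(self, purine_core):
        from fluxdesign.synthetic import default_medium

        m = apply_medium(purine_core, default_medium())
        assert m.reaction("EX_glc").lower_bound == -10
        for r in m.exchanges:
            if r.id != "EX_glc":
                assert r.lower_bound == 0

    def test_published_uptake_caps_map_to_negative_lower_bounds(self):
        mets = [Metabolite(x, compartment="e") for x in
                ["glc", "o2", "co2", "pi", "so4", "nh3", "h2o"]]
        rxns = [Reaction(f"EX_{m.id}", {m.id: -1}, -1000, 1000) for m in mets]
        model = MetabolicModel(mets, rxns, [], objective_id="EX_glc")
        medium = aerobic_minimal_medium(
            "EX_glc", "EX_o2", "EX_co2", "EX_pi", "EX_so4", "EX_nh3",
            free_ion_exchanges=["EX_h2o"],
        )
        out = apply_medium(model, medium)
        assert out.reaction("EX_glc").lower_bound == -9.5
        assert out.reaction("EX_o2").lower_bound == -10.9
        assert out.reaction("EX_co2").lower_bound == -15.1
        assert out.reaction("EX_pi").lower_bound == -5
        assert out.reaction("EX_so4").lower_bound == -5
        assert out.reaction("EX_nh3").lower_bound == -5
        assert out.reaction("EX_h2o").lower_bound == -1000

    def test_empty_medium_closes_all_uptake_and_zeroes_growth(self):
        # a toy without obligatory internal fluxes: no carbon source, no growth
        toy = make_toy(seed=11)
        closed = apply_medium(toy, MediumSpec(bounds={}, default_closed=True))
        sol = solve_fba(closed)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_non_exchange_reaction_rejected(self, purine_core):
        with pytest.raises(ValueError, match="non-exchange"):
            apply_medium(purine_core, MediumSpec(bounds={"PGI": (0, 1)}))

    def test_idempotent_and_commutes_with_knockout(self, purine_core):
        from fluxdesign.synthetic import default_medium

        med = default_medium()
        once = apply_medium(purine_core, med)
        assert apply_medium(once, med) == once
        a = knockout_genes(apply_medium(purine_core, med), {"drm"})
        b = apply_medium(knockout_genes(purine_core, {"drm"}), med)
        assert a == b


class TestKnockouts:
    def test_drm_knockout_zeroes_phosphopentomutase(self, purine_core):
        m = knockout_genes(purine_core, {"drm"})
        r = m.reaction("PPM")
        assert (r.lower_bound, r.upper_bound) == (0.0, 0.0)

    def test_isozyme_pair_protects_reaction(self, purine_core):
        m = knockout_genes(purine_core, {"deoD"})
        assert m.reaction("PNP").upper_bound > 0
        m2 = knockout_genes(purine_core, {"deoD", "pupG"})
        assert m2.reaction("PNP").upper_bound == 0

    def test_complex_dies_with_any_subunit(self, purine_core):
        for g in ["zwf", "ykgB"]:
            assert knockout_genes(purine_core, {g}).reaction("ZWF").upper_bound == 0

    def test_empty_knockout_is_identity(self, purine_core):
        assert knockout_genes(purine_core, set()) == purine_core

    def test_unknown_gene_listed(self, purine_core):
        with pytest.raises(KeyError, match="nope"):
            knockout_genes(purine_core, {"nope"})

    def test_reaction_and_gene_knockouts_agree(self, purine_core):
        by_gene = knockout_genes(purine_core, {"ywjH", "drm"})
        by_rxn = knockout_reactions(purine_core, {"TAL", "PPM"})
        assert by_gene == by_rxn

    def test_knockouts_commute_and_are_idempotent(self, purine_core):
        a = knockout_genes(knockout_genes(purine_core, {"drm"}), {"ywjH"})
        b = knockout_genes(knockout_genes(purine_core, {"ywjH"}), {"drm"})
        assert a == b == knockout_genes(purine_core, {"drm", "ywjH"})
        assert knockout_genes(a, {"drm"}) == a


class TestIO:
    @pytest.mark.parametrize("fmt,suffix", [("json", "m.json"), ("sbml", "m.xml"), ("tsv", "mdir")])
    def test_write_load_identity(self, tmp_path, purine_core, fmt, suffix):
        model = purine_core
        if fmt == "tsv":  # the TSV dialect does not carry reaction display names
            model = MetabolicModel(
                metabolites=model.metabolites,
                reactions=[
                    Reaction(r.id, r.stoichiometry, r.lower_bound, r.upper_bound,
                             gpr=r.gpr, subsystem=r.subsystem)
                    for r in model.reactions
                ],
                genes=model.genes,
                objective_id=model.objective_id,
            )
        path = tmp_path / suffix
        fio.write_model(model, path, fmt)
        assert fio.load_model(path, fmt) == model

    def test_random_toys_round_trip_sbml(self, tmp_path):
        for seed in [0, 5]:
            toy = make_toy(seed=seed)
            fio.write_model(toy, tmp_path / f"t{seed}.xml")
            assert fio.load_model(tmp_path / f"t{seed}.xml") == toy

    def test_infinite_bounds_sentinel_round_trips(self, tmp_path):
        model = tiny_model(
            reactions=[
                Reaction("EX_a", {"a": -1}, -math.inf, math.inf),
                Reaction("DM_b", {"b": -1}, 0, 1000),
            ],
            objective_id="DM_b",
            genes=[],
        )
        fio.write_model(model, tmp_path / "inf.json")
        text = (tmp_path / "inf.json").read_text()
        assert '"-inf"' in text and '"inf"' in text
        back = fio.load_model(tmp_path / "inf.json")
        assert back.reaction("EX_a").lower_bound == -math.inf
        assert back == model

    def test_golden_json_serialisation(self, purine_core):
        expected = json.loads((DATA / "purine_core.json").read_text())
        assert fio.model_to_json_dict(purine_core) == expected

    def test_golden_reactions_tsv(self, tmp_path, purine_core):
        fio.write_model(purine_core, tmp_path / "tsv", "tsv")
        got = (tmp_path / "tsv" / "reactions.tsv").read_text()
        assert got == (DATA / "purine_core_reactions.tsv").read_text()
        header = got.splitlines()[3]
        assert header.split("\t") == [
            "reaction_id", "equation", "lower_bound", "upper_bound", "gpr", "subsystem",
        ]

    def test_bit_stable_output(self, tmp_path, purine_core):
        fio.write_model(purine_core, tmp_path / "a.json")
        fio.write_model(purine_core, tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_medium_yaml_and_tsv_readers(self, tmp_path):
        (tmp_path / "med.yaml").write_text(
            "default_closed: true\nexchanges:\n  EX_glc: [-9.5, 1000]\n"
        )
        med = fio.read_medium(tmp_path / "med.yaml")
        assert med.bounds["EX_glc"] == (-9.5, 1000)
        (tmp_path / "med.tsv").write_text(
            "exchange_id\tlower_bound\tupper_bound\nEX_glc\t-9.5\t1000\n"
        )
        assert fio.read_medium(tmp_path / "med.tsv").bounds == med.bounds

    def test_bounds_table_round_trip(self, tmp_path, purine_core):
        from fluxdesign.synthetic import thirteen_c_bounds_fixture

        table = thirteen_c_bounds_fixture(purine_core)
        fio.write_bounds_table(table, tmp_path / "b.tsv")
        assert fio.read_bounds_table(tmp_path / "b.tsv") == table

    def test_model_summary_counts(self, purine_core):
        summary = fio.model_summary(purine_core)
        # DM_imp counts as a boundary reaction under the single-metabolite
        # coefficient -1 convention, alongside the six EX_ exchanges
        assert summary == {"metabolites": 17, "reactions": 23, "genes": 12, "exchanges": 7}
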