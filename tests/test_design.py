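"""GDLS knockout search, deletion-matrix encoding, and MUST classification."""

import itertools

import numpy as np
import pytest

from conftest import make_toy
from fluxdesign.design import (
    GdlsConfig,
    build_deletion_matrix,
    deletion_bounds,
    enumerate_knockouts_bruteforce,
    evaluate_knockout,
    gdls_search,
    must_singles,
)
from fluxdesign.fba import solve_fba
from fluxdesign.model import knockout_genes
from fluxdesign.synthetic import thirteen_c_bounds_fixture


def toy_cfg(toy, **kw):
    defaults = dict(
        outer_objective_id="DM_p",
        inner_objective_id="BIO",
        max_knockouts=2,
        min_growth=0.0,
        neighborhood_size=None,
        search_paths=1,
    )
    defaults.update(kw)
    return GdlsConfig(**defaults)


class TestDeletionMatrix:
    def test_single_gene_reactions_give_permutation_like_incidence(self, purine_core):
        dm = build_deletion_matrix(purine_core)
        j = dm.reactions.index("PPM")
        col = dm.G[:, j]
        assert col.sum() == 1
        assert dm.genes[int(np.argmax(col))] == "drm"

    def test_isozyme_reaction_has_no_single_disabling_gene(self, purine_core):
        dm = build_deletion_matrix(purine_core)
        j = dm.reactions.index("PNP")
        assert dm.G[:, j].sum() == 0
        assert frozenset({"deoD", "pupG"}) in dm.cut_sets[j]

    def test_complex_reaction_disabled_by_each_subunit(self, purine_core):
        dm = build_deletion_matrix(purine_core)
        j = dm.reactions.index("ZWF")
        hit = {dm.genes[l] for l in np.nonzero(dm.G[:, j])[0]}
        assert hit == {"zwf", "ykgB"}

    def test_bound_equivalence_with_gpr_knockouts_up_to_two_genes(self, purine_core):
        dm = build_deletion_matrix(purine_core)
        genes = purine_core.genes
        for k in range(0, 3):
            for combo in itertools.combinations(genes, k):
                knocked = frozenset(combo)
                via_matrix = deletion_bounds(dm, knocked)
                via_gpr = {
                    r.id: (r.lower_bound, r.upper_bound)
                    for r in knockout_genes(purine_core, knocked).reactions
                }
                assert via_matrix == via_gpr, f"disagreement for {sorted(knocked)}"


class TestBruteForce:
    def test_single_knockout_ranking_follows_pathway_logic(self, purine_core, gdls_cfg):
        """Releasing the obligatory drm turnover loop saves the most carbon,
        so drm tops the C=1 ranking."""
        ranked = enumerate_knockouts_bruteforce(purine_core, purine_core.genes, 1, gdls_cfg)
        assert ranked[0].knocked_genes == frozenset({"drm"})
        wild = next(s for s in ranked if not s.knocked_genes)
        assert ranked[0].predicted_target_flux > wild.predicted_target_flux

    def test_growth_floor_filters_lethal_combinations(self, purine_core, gdls_cfg):
        ranked = enumerate_knockouts_bruteforce(purine_core, ["glcK"], 1, gdls_cfg)
        # glucokinase knockout starves the cell below the growth floor
        assert all(s.knocked_genes != frozenset({"glcK"}) for s in ranked)

    def test_enumeration_guard(self, purine_core, gdls_cfg):
        with pytest.raises(ValueError, match="guard"):
            enumerate_knockouts_bruteforce(
                purine_core, purine_core.genes, 12, gdls_cfg, subset_guard=100
            )


class TestGdls:
    def test_zero_budget_returns_wild_type(self, purine_core, gdls_cfg):
        cfg = GdlsConfig(
            outer_objective_id="DM_imp", inner_objective_id="BIOMASS", max_knockouts=0
        )
        out = gdls_search(purine_core, cfg)
        assert len(out) == 1
        assert out[0].knocked_genes == frozenset()
        assert out[0].predicted_growth == pytest.approx(
            solve_fba(purine_core).objective_value
        )

    def test_unreachable_growth_floor_yields_empty_list(self, purine_core):
        cfg = GdlsConfig(
            outer_objective_id="DM_imp", inner_objective_id="BIOMASS",
            max_knockouts=2, min_growth=5.0,
        )
        assert gdls_search(purine_core, cfg) == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5, 6, 7])
    def test_matches_bruteforce_on_random_toys(self, seed):
        toy = make_toy(seed=seed, n_extra=6)
        cfg = toy_cfg(toy)
        brute = enumerate_knockouts_bruteforce(toy, toy.genes, 2, cfg)
        found = gdls_search(toy, cfg)
        assert brute and found
        assert found[0].predicted_target_flux == pytest.approx(
            brute[0].predicted_target_flux, rel=1e-6, abs=1e-6
        )
        # cardinality is only determined when some knockout strictly beats the
        # wild type; otherwise every subset ties and the "best" set is arbitrary
        wild = next(s for s in brute if not s.knocked_genes)
        if brute[0].predicted_target_flux > wild.predicted_target_flux + 1e-6:
            assert len(found[0].knocked_genes) == len(brute[0].knocked_genes)

    def test_local_search_reaches_global_optimum_on_fixture(self, purine_core, gdls_cfg):
        local = GdlsConfig(
            outer_objective_id="DM_imp", inner_objective_id="BIOMASS",
            max_knockouts=2, min_growth=0.05, neighborhood_size=1, search_paths=1,
        )
        out = gdls_search(purine_core, local)
        brute = enumerate_knockouts_bruteforce(purine_core, purine_core.genes, 2, gdls_cfg)
        assert out[0].predicted_target_flux == pytest.approx(
            brute[0].predicted_target_flux, rel=1e-6
        )

    def test_budget_and_floor_monotonicity(self, purine_core, gdls_cfg):
        def best(C, floor):
            cfg = GdlsConfig(
                outer_objective_id="DM_imp", inner_objective_id="BIOMASS",
                max_knockouts=C, min_growth=floor, neighborhood_size=None,
            )
            out = gdls_search(purine_core, cfg)
            return out[0].predicted_target_flux if out else -np.inf

        assert best(2, 0.05) >= best(1, 0.05) - 1e-9
        assert best(1, 0.9) <= best(1, 0.05) + 1e-9

    def test_strategies_reproduce_under_independent_resimulation(self, purine_core, gdls_cfg):
        for s in gdls_search(purine_core, gdls_cfg):
            status, mu, target = evaluate_knockout(
                purine_core, s.knocked_genes, "DM_imp", "BIOMASS", s.tie_break
            )
            assert status == "optimal"
            assert mu == pytest.approx(s.predicted_growth, rel=1e-6, abs=1e-9)
            assert target == pytest.approx(s.predicted_target_flux, rel=1e-6, abs=1e-9)

    def test_pessimistic_tie_break_never_exceeds_optimistic(self, purine_core):
        for knocked in [frozenset(), frozenset({"drm"}), frozenset({"drm", "ywjH"})]:
            _, _, opt = evaluate_knockout(purine_core, knocked, "DM_imp", "BIOMASS",
                                          "optimistic")
            _, _, pes = evaluate_knockout(purine_core, knocked, "DM_imp", "BIOMASS",
                                          "pessimistic")
            assert pes <= opt + 1e-9


class TestMustSingles:
    def test_zero_floor_leaves_all_unclassified(self, purine_core):
        table = thirteen_c_bounds_fixture(purine_core)
        # with no overproduction requirement the engineered polytope contains
        # the wild-type one, so no range can be disjoint
        mc = must_singles(purine_core, table, 0.0, target_id="DM_imp")
        up_or_down = [c for c in mc.classes.values() if c in {"must_up", "must_down"}]
        assert up_or_down == []

    def test_oxidative_ppp_entry_is_must_up_near_max(self, purine_core):
        table = thirteen_c_bounds_fixture(purine_core)
        floor = 0.9 * solve_fba(purine_core, "DM_imp", "max").objective_value
        mc = must_singles(purine_core, table, floor, target_id="DM_imp")
        assert mc.classes["ZWF"] == "must_up"
        assert mc.engineered_range["ZWF"][0] > mc.wild_type_range["ZWF"][1]

    def test_identical_ranges_stay_unclassified(self, purine_core):
        # the biomass cap binds identically in both conditions at floor 0
        mc = must_singles(purine_core, {"EX_glc": (-10.0, 1000.0)}, 0.0,
                          target_id="DM_imp", rxn_ids=["EX_glc"])
        assert mc.classes["EX_glc"] == "unclassified"

    def test_floor_above_theoretical_max_rejected(self, purine_core):
        table = thirteen_c_bounds_fixture(purine_core)
        with pytest.raises(ValueError, match="floor"):
            must_singles(purine_core, table, 1e3, target_id="DM_imp")

    def test_invariant_to_reaction_order_and_unit_rescaling(self, purine_core):
        table = thirteen_c_bounds_fixture(purine_core)
        floor = 0.9 * solve_fba(purine_core, "DM_imp", "max").objective_value
        base = must_singles(purine_core, table, floor, target_id="DM_imp")

        reordered = purine_core.copy()
        reordered.reactions = list(reversed(reordered.reactions))
        again = must_singles(reordered, table, floor, target_id="DM_imp")
        assert again.classes == base.classes

        lam = 2.0
        scaled = purine_core.with_bounds(
            {r.id: (lam * r.lower_bound, lam * r.upper_bound) for r in purine_core.reactions}
        )
        scaled_table = {rid: (lam * lo, lam * hi) for rid, (lo, hi) in table.items()}
        rescaled = must_singles(scaled, scaled_table, lam * floor, target_id="DM_imp")
        assert rescaled.reactions_in("must_up") == base.reactions_in("must_up")
        assert rescaled.reactions_in("must_down") == base.reactions_in("must_down")
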