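"""FBA, FVA, yields and production envelopes against independent oracles."""

import numpy as np
import pytest

from conftest import make_toy
from fluxdesign.fba import (
    FluxSolution,
    UndefinedYieldError,
    flux_variability,
    production_envelope,
    solve_fba,
    theoretical_maxima,
    yield_mol_per_mol,
)
from fluxdesign.model import MediumSpec, apply_medium
from oracles import fba_oracle


class TestSolveFba:
    def test_fixture_matches_dense_simplex_oracle(self, purine_core):
        for objective in ["BIOMASS", "DM_imp", "EX_ins"]:
            mine = solve_fba(purine_core, objective, "max")
            status, ref, _ = fba_oracle(purine_core, objective, "max")
            assert mine.status == status == "optimal"
            assert mine.objective_value == pytest.approx(ref, rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_toys_match_oracle(self, seed):
        toy = make_toy(seed=seed)
        mine = solve_fba(toy)
        status, ref, _ = fba_oracle(toy, toy.objective_id, "max")
        assert mine.status == status == "optimal"
        assert mine.objective_value == pytest.approx(ref, rel=1e-6, abs=1e-9)

    def test_closed_uptakes_give_zero_objective(self):
        toy = apply_medium(make_toy(seed=2), MediumSpec(bounds={}))
        sol = solve_fba(toy)
        assert sol.optimal and sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_reported_as_status(self, purine_core):
        # closing glucose starves the obligatory turnover fluxes
        closed = apply_medium(purine_core, MediumSpec(bounds={}))
        sol = solve_fba(closed)
        assert sol.status == "infeasible"
        assert sol.objective_value is None

    def test_steady_state_residual_is_tiny(self, purine_core):
        sol = solve_fba(purine_core)
        S = purine_core.stoichiometric_matrix()
        v = np.array([sol.fluxes[r] for r in purine_core.reaction_ids])
        assert np.abs(S @ v).max() < 1e-6

    def test_cobra_cross_validation(self, tmp_path, purine_core):
        """Independent implementation route: the same model through cobrapy."""
        cobra = pytest.importorskip("cobra")
        from fluxdesign.io import write_model

        write_model(purine_core, tmp_path / "m.xml")
        cm = cobra.io.read_sbml_model(str(tmp_path / "m.xml"))
        assert cm.optimize().objective_value == pytest.approx(
            solve_fba(purine_core).objective_value, rel=1e-6
        )
        cm.objective = "DM_imp"
        assert cm.optimize().objective_value == pytest.approx(
            solve_fba(purine_core, "DM_imp", "max").objective_value, rel=1e-6
        )


class TestYield:
    def test_published_style_arithmetic(self):
        sol = FluxSolution("optimal", 1.450, {"DM_imp": 1.450, "EX_glc": -1.799})
        assert yield_mol_per_mol(sol, "DM_imp", "EX_glc") == pytest.approx(0.806, abs=5e-4)

    def test_zero_target_gives_zero(self):
        sol = FluxSolution("optimal", 0.0, {"DM_imp": 0.0, "EX_glc": -1.0})
        assert yield_mol_per_mol(sol, "DM_imp", "EX_glc") == 0.0

    def test_zero_uptake_is_undefined(self):
        sol = FluxSolution("optimal", 1.0, {"DM_imp": 1.0, "EX_glc": 0.0})
        with pytest.raises(UndefinedYieldError):
            yield_mol_per_mol(sol, "DM_imp", "EX_glc")

    def test_fixture_yield_is_hand_traceable(self, purine_core):
        # each IMP costs 1 glucose for its ribose (one carbon lost as CO2 in
        # the oxidative PPP) plus half a glucose for the g3p of the base, so
        # the molar yield can never reach 1
        sol = solve_fba(purine_core, "DM_imp", "max")
        y = yield_mol_per_mol(sol, "DM_imp", "EX_glc")
        assert 0 < y < 1
        assert y == pytest.approx(sol.objective_value / 10.0, rel=1e-6)


class TestFluxVariability:
    def test_blocked_reaction_has_zero_range(self, purine_core):
        m = purine_core.with_bounds({"PGI": (0.0, 0.0)})
        assert flux_variability(m, ["PGI"], 1.0)["PGI"] == pytest.approx((0.0, 0.0))

    def test_objective_pinned_at_full_optimum(self, purine_core):
        rng = flux_variability(purine_core, ["BIOMASS"], 1.0)["BIOMASS"]
        mu = solve_fba(purine_core).objective_value
        assert rng[0] == pytest.approx(mu, abs=1e-6)
        assert rng[1] == pytest.approx(mu, abs=1e-6)

    def test_fraction_zero_equals_raw_polytope_ranges(self, purine_core):
        ranges = flux_variability(purine_core, ["GLK", "ZWF"], 0.0)
        for rid, (lo, hi) in ranges.items():
            _, ref_lo, _ = fba_oracle(purine_core, rid, "min")
            _, ref_hi, _ = fba_oracle(purine_core, rid, "max")
            assert lo == pytest.approx(ref_lo, abs=1e-6)
            assert hi == pytest.approx(ref_hi, abs=1e-6)


class TestProductionEnvelope:
    def test_endpoints_equal_fba_solutions(self, purine_core):
        env = production_envelope(purine_core, "BIOMASS", "DM_imp", n_points=2)
        assert env.growth_grid[-1] == pytest.approx(
            solve_fba(purine_core).objective_value, rel=1e-9
        )
        assert max(env.max_target) == pytest.approx(
            solve_fba(purine_core, "DM_imp", "max").objective_value, rel=1e-6
        )

    def test_upper_boundary_concave_and_competitive(self, purine_core):
        env = production_envelope(purine_core, "BIOMASS", "DM_imp", n_points=15)
        g, f = np.array(env.growth_grid), np.array(env.max_target)
        # every interior point lies on or above the chord of its neighbours
        for i in range(1, len(g) - 1):
            chord = f[i - 1] + (f[i + 1] - f[i - 1]) * (g[i] - g[i - 1]) / (g[i + 1] - g[i - 1])
            assert f[i] >= chord - 1e-6
        assert f[-1] < f[0] - 1e-6  # growth competes with the product
        assert np.all(np.array(env.max_target) >= np.array(env.min_target) - 1e-9)

    def test_needs_at_least_two_points(self, purine_core):
        with pytest.raises(ValueError):
            production_envelope(purine_core, "BIOMASS", "DM_imp", n_points=1)


class TestLpProperties:
    def test_added_constraints_never_help(self, purine_core):
        """Maximisation objectives are monotone under medium restriction."""
        rich = solve_fba(purine_core).objective_value
        for glc in [-7.5, -5.0, -2.5]:
            poorer = apply_medium(
                purine_core, MediumSpec(bounds={"EX_glc": (glc, 1000.0)})
            )
            val = solve_fba(poorer).objective_value
            assert val <= rich + 1e-9
            rich = val

    @pytest.mark.parametrize("lam", [0.5, 2.0])
    def test_homogeneity_under_uniform_bound_scaling(self, lam):
        toy = make_toy(seed=7)
        base = solve_fba(toy).objective_value
        scaled = toy.with_bounds(
            {r.id: (lam * r.lower_bound, lam * r.upper_bound) for r in toy.reactions}
        )
        assert solve_fba(scaled).objective_value == pytest.approx(lam * base, rel=1e-9)

    def test_theoretical_maxima_composes_three_calls(self, purine_core):
        tm = theoretical_maxima(purine_core, "BIOMASS", "DM_imp", "EX_glc")
        assert tm.mu_max == pytest.approx(solve_fba(purine_core).objective_value)
        tgt = solve_fba(purine_core, "DM_imp", "max")
        assert tm.target_max == pytest.approx(tgt.objective_value)
        assert tm.yield_at_target_max == pytest.approx(
            yield_mol_per_mol(tgt, "DM_imp", "EX_glc")
        )

    def test_growth_fixed_mode(self, purine_core):
        free = theoretical_maxima(purine_core, "BIOMASS", "DM_imp", "EX_glc")
        pinned = theoretical_maxima(purine_core, "BIOMASS", "DM_imp", "EX_glc",
                                    growth_fixed=0.0)
        assert pinned.target_max == pytest.approx(free.target_max, rel=1e-6)
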