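"""Speciation solver: mass balance, oracle agreement, constant refinement."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fetiron import (
    SolutionConditions,
    SpeciesModel,
    TitrationFit,
    distribution_curve,
    refine_constants,
    solve_speciation,
)
from fetiron.speciation import FE_SPECIES, simulate_absorbance, simulate_base_volume
from fetiron.synth import NoiseSpec, make_titration

from oracles import speciation_grid_oracle

LOGKS = lambda m: (m.logK1H, m.logK2H, m.logK_FeL, m.logK_FeL2, m.logK_FeL3, m.logK_FeL2Hm1)


def _mass_balance_errors(model, state, cond):
    c = state.concentrations
    fe_sum = c["Fe"] + c["FeL"] + c["FeL2"] + c["FeL3"] + c["FeL2Hm1"]
    l_sum = (
        c["L"] + c["HL"] + c["H2L"]
        + c["FeL"] + 2 * c["FeL2"] + 3 * c["FeL3"] + 2 * c["FeL2Hm1"]
    )
    fe_err = abs(fe_sum - cond.total_Fe) / max(cond.total_Fe, 1e-300)
    l_err = abs(l_sum - cond.total_L) / max(cond.total_L, 1e-300)
    return fe_err, l_err


class TestSolveSpeciation:
    def test_no_metal_distributes_ligand_by_protonation_only(self, table1):
        cond = SolutionConditions(total_Fe=0.0, total_L=1e-3, pH=7.0)
        state = solve_speciation(table1, cond)
        for sp in FE_SPECIES:
            assert state[sp] == 0.0
        # closed-form ligand distribution at fixed pH
        h = 1e-7
        aH = 1 + 10**table1.logK1H * h + 10 ** (table1.logK1H + table1.logK2H) * h * h
        assert state["L"] == pytest.approx(1e-3 / aH, rel=1e-12)
        assert state["HL"] == pytest.approx(1e-3 * 10**table1.logK1H * h / aH, rel=1e-12)

    def test_bis_complex_dominates_in_mid_pH_window(self, table1):
        # 1:50 relaxometric conditions: the bis complex carries >90% of Fe
        state = solve_speciation(table1, SolutionConditions(1.88e-3, 94.0e-3, 4.3))
        assert state.fraction("FeL2") >= 0.90

    def test_agrees_with_grid_bisection_oracle_at_physiological_pH(self, table1):
        state = solve_speciation(table1, SolutionConditions(1e-4, 5e-4, 7.4))
        oracle = speciation_grid_oracle(LOGKS(table1), 1e-4, 5e-4, 7.4, n_grid=1_000_000)
        for sp in ("L", "Fe", "FeL2", "FeL3"):
            assert state[sp] == pytest.approx(oracle[sp], rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_agreement_on_random_conditions(self, table1, seed):
        # 10 instances per seed -> 50 random (totals, pH) draws
        rng = np.random.default_rng(1234 + seed)
        for _ in range(10):
            FeT = 10 ** rng.uniform(-5, -2)
            LT = FeT * 10 ** rng.uniform(0.3, 2)
            pH = rng.uniform(1.0, 10.0)
            state = solve_speciation(table1, SolutionConditions(FeT, LT, pH))
            oracle = speciation_grid_oracle(LOGKS(table1), FeT, LT, pH, n_grid=100_000)
            for sp in ("L", "FeL", "FeL2", "FeL3"):
                if oracle[sp] > 1e-30:
                    assert state[sp] == pytest.approx(oracle[sp], rel=1e-6), (sp, pH)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        logFe=st.floats(-6, -2),
        ratio=st.floats(0.2, 2.0),
        pH=st.floats(0.5, 11.0),
    )
    def test_mass_balances_hold_everywhere(self, table1, logFe, ratio, pH):
        cond = SolutionConditions(10**logFe, 10**logFe * 10**ratio, pH)
        state = solve_speciation(table1, cond)
        fe_err, l_err = _mass_balance_errors(table1, state, cond)
        assert fe_err < 1e-10 and l_err < 1e-10
        assert all(v >= 0 for v in state.concentrations.values())
        assert sum(state.fe_fractions.values()) == pytest.approx(1.0, abs=1e-10)

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            SolutionConditions(total_Fe=-1e-3, total_L=1e-3, pH=7.0)


class TestDistributionCurve:
    def test_rows_sum_to_one_and_match_pointwise_solver(self, table1):
        grid = np.linspace(1.0, 9.0, 17)
        table = distribution_curve(table1, 0.2e-3, 9.0e-3, grid)
        frac_cols = [f"x_{s}" for s in FE_SPECIES]
        assert np.allclose(table[frac_cols].sum(axis=1), 1.0, atol=1e-10)
        state = solve_speciation(table1, SolutionConditions(0.2e-3, 9.0e-3, 5.0))
        row = table.iloc[np.argmin(np.abs(grid - 5.0))]
        assert row["x_FeL2"] == pytest.approx(state.fraction("FeL2"), rel=1e-12)

    def test_crossover_pH_matches_bisection_oracle(self, table1):
        # FeL/FeL2 crossover located independently by bisection on the
        # fraction difference computed through the grid oracle
        def frac_diff(pH):
            o = speciation_grid_oracle(LOGKS(table1), 0.2e-3, 9.0e-3, pH, n_grid=20_000)
            tot = o["Fe"] + o["FeL"] + o["FeL2"] + o["FeL3"] + o["FeL2Hm1"]
            return (o["FeL"] - o["FeL2"]) / tot

        lo, hi = 1.0, 5.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if frac_diff(lo) * frac_diff(mid) <= 0:
                hi = mid
            else:
                lo = mid
        crossover_oracle = 0.5 * (lo + hi)

        grid = np.linspace(1.0, 5.0, 2001)
        table = distribution_curve(table1, 0.2e-3, 9.0e-3, grid)
        diff = table["x_FeL"] - table["x_FeL2"]
        i = int(np.nonzero(np.diff(np.sign(diff)))[0][0])
        assert grid[i] == pytest.approx(crossover_oracle, abs=2e-3)

    def test_fractions_continuous_in_pH(self, table1):
        grid = np.arange(0.5, 10.5, 0.01)
        table = distribution_curve(table1, 0.2e-3, 9.0e-3, grid)
        for s in FE_SPECIES:
            assert np.max(np.abs(np.diff(table[f"x_{s}"]))) < 0.02

    def test_weaker_tris_constant_lowers_tris_fraction(self, table1):
        weak = table1.with_constants(logK_FeL3=table1.logK_FeL3 - 5)
        base = solve_speciation(table1, SolutionConditions(0.2e-3, 9.0e-3, 8.0))
        mod = solve_speciation(weak, SolutionConditions(0.2e-3, 9.0e-3, 8.0))
        assert mod.fraction("FeL3") < base.fraction("FeL3")

    def test_non_monotone_grid_rejected(self, table1):
        with pytest.raises(ValueError):
            distribution_curve(table1, 1e-3, 2e-3, [5.0, 4.0, 6.0])


class TestSimulateObservable:
    def test_zero_epsilons_give_zero_absorbance(self, table1):
        A = simulate_absorbance(
            table1, np.linspace(2, 8, 7), 0.19e-3, 9.1e-3,
            {sp: 0.0 for sp in ("FeL", "FeL2", "FeL3", "FeL2Hm1")},
        )
        assert np.all(A == 0.0)

    def test_beer_lambert_identity_single_species(self, table1):
        # conditions where essentially all Fe is FeL2: A = eps * [FeL2] * l
        state = solve_speciation(table1, SolutionConditions(0.19e-3, 9.1e-3, 4.3))
        A = simulate_absorbance(
            table1, np.array([4.3]), 0.19e-3, 9.1e-3,
            {"FeL": 0.0, "FeL2": 1000.0, "FeL3": 0.0, "FeL2Hm1": 0.0},
        )
        assert A[0] == pytest.approx(1000.0 * state["FeL2"], rel=1e-12)

    def test_missing_epsilon_for_present_species_raises(self, table1):
        with pytest.raises(ValueError, match="FeL2"):
            simulate_absorbance(table1, np.array([4.3]), 0.19e-3, 9.1e-3, {"FeL": 500.0})

    def test_absorbance_inflections_track_species_transitions(self, table1):
        # A(pH) under the standard titration design changes monotonically
        # between consecutive species plateaus: the number of sign changes
        # of dA/dpH cannot exceed the number of species transitions (3)
        pH = np.linspace(1.0, 9.5, 171)
        A = simulate_absorbance(
            table1, pH, 0.19e-3, 9.1e-3,
            {"FeL": 1800.0, "FeL2": 3200.0, "FeL3": 2200.0, "FeL2Hm1": 2000.0},
        )
        slope = np.diff(A)
        sign_changes = np.sum(np.diff(np.sign(slope[np.abs(slope) > 1e-9])) != 0)
        assert sign_changes <= 3

    def test_base_volume_increases_with_pH(self, table1):
        pH = np.linspace(2.5, 10.5, 9)
        vb = simulate_base_volume(
            table1, pH, 2e-3, 4e-3, initial_acid=5e-3,
            titrant_conc=0.1, initial_volume=6e-3,
        )
        assert np.all(np.diff(vb) > 0)


class TestRefineConstants:
    def test_noiseless_recovery_of_single_constant(self, table1):
        data = make_titration(table1)
        start = table1.with_constants(logK_FeL2=13.8)
        res = refine_constants([data], start, free=["logK_FeL2"])
        assert res.success
        assert res.params["logK_FeL2"] == pytest.approx(14.49, abs=1e-3)
        assert res.stderr["logK_FeL2"] < 1e-3

    def test_noiseless_recovery_any_single_constant(self, table1):
        data = make_titration(table1)
        for name, off in [("logK_FeL", 0.4), ("logK_FeL3", -0.4), ("logK_FeL2Hm1", 0.3)]:
            start = table1.with_constants(**{name: getattr(table1, name) + off})
            res = refine_constants([data], start, free=[name])
            assert res.params[name] == pytest.approx(getattr(table1, name), abs=1e-3), name

    def test_zero_free_parameters_echoes_model(self, table1):
        data = make_titration(table1)
        res = refine_constants([data], table1, free=[])
        assert res.success and res.params == {}
        assert res.objective == pytest.approx(0.0, abs=1e-16)
        assert res.fixed["logK_FeL2"] == table1.logK_FeL2

    def test_noisy_replicates_unbiased_for_logK1H(self, table1):
        # replicate study: sigma_A = 0.005 absolute, recovery of logK1H;
        # bounds frozen from a pre-build replicate run of the same design
        recovered = []
        for seed in range(1, 9):
            data = make_titration(
                table1, noise=NoiseSpec("absolute-gaussian", 0.005, seed)
            )
            start = table1.with_constants(logK1H=12.10)
            res = refine_constants([data], start, free=["logK1H"])
            recovered.append(res.params["logK1H"])
        recovered = np.asarray(recovered)
        assert abs(np.mean(recovered) - table1.logK1H) < 0.05
        assert np.std(recovered) < 0.1

    def test_epsilon_and_constant_joint_refinement(self, table1):
        data = make_titration(table1)
        start = table1.with_constants(logK_FeL2=14.0)
        fit = TitrationFit(
            [data], start, free=["logK_FeL2"], free_epsilons=[("FeL2", 562.0)]
        )
        res = fit.fit()
        assert res.params["logK_FeL2"] == pytest.approx(14.49, abs=2e-3)
        assert res.params["eps_FeL2_562"] == pytest.approx(3200.0, rel=2e-3)

    def test_invalid_free_name_rejected(self, table1):
        with pytest.raises(ValueError):
            TitrationFit([make_titration(table1)], table1, free=["logK_bogus"])

    def test_summary_renders(self, table1):
        res = refine_constants([make_titration(table1)], table1, free=["logK_FeL2"])
        text = res.summary()
        assert "logK_FeL2" in text and "converged" in text
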