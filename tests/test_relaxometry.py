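"""Relaxivity forward model: limits, scaling laws, oracle equivalence."""
import numpy as np
import pytest

from fetiron import (
    FieldPoint,
    RelaxParams,
    electron_relaxation,
    inner_sphere_r1,
    nmrd_profile,
    outer_sphere_r1,
    second_sphere_r1,
    temperature_scale,
    total_r1,
)
from fetiron.constants import OMEGA_S_OVER_OMEGA_I, T_REF

from oracles import (
    electron_relax_oracle,
    eyring_tau,
    relax_params_to_oracle_dict,
    total_r1_oracle,
)


class TestElectronRelaxation:
    def test_zero_field_symmetry(self):
        T1e, T2e = electron_relaxation(0.0, 12.2e20, 5.6e-12)
        assert T1e == pytest.approx(T2e, rel=1e-14)

    def test_zero_zfs_disables_electron_relaxation(self):
        T1e, T2e = electron_relaxation(1e11, 0.0, 5.6e-12)
        assert np.isinf(T1e) and np.isinf(T2e)

    def test_matches_closed_form_oracle_at_60MHz(self):
        omega_S = OMEGA_S_OVER_OMEGA_I * 2 * np.pi * 60e6
        got = electron_relaxation(omega_S, 12.2e20, 5.6e-12)
        want = electron_relax_oracle(omega_S, 12.2e20, 5.6e-12)
        assert got[0] == pytest.approx(want[0], rel=1e-12)
        assert got[1] == pytest.approx(want[1], rel=1e-12)

    def test_T1e_exceeds_T2e_at_high_field(self):
        omega_S = OMEGA_S_OVER_OMEGA_I * 2 * np.pi * 500e6
        T1e, T2e = electron_relaxation(omega_S, 9.7e20, 6.9e-12)
        assert T1e > T2e


class TestTemperatureScale:
    @pytest.mark.parametrize("law", ["arrhenius-time", "arrhenius-rate", "eyring-exchange"])
    def test_identity_at_reference_temperature(self, law):
        assert temperature_scale(3.14, 20e3, T_REF, law) == pytest.approx(3.14, rel=1e-14)

    def test_correlation_times_shrink_with_temperature(self):
        assert temperature_scale(70e-12, 16e3, 283.0, "arrhenius-time") > temperature_scale(
            70e-12, 16e3, 310.0, "arrhenius-time"
        )

    def test_eyring_exchange_matches_oracle_at_310K(self):
        got = temperature_scale(272e-9, 56.2e3, 310.0, "eyring-exchange")
        assert got == pytest.approx(eyring_tau(272e-9, 56.2e3, 310.0), rel=1e-12)

    def test_unknown_law_rejected(self):
        with pytest.raises(ValueError):
            temperature_scale(1.0, 0.0, 298.0, "linear")


class TestSphereContributions:
    def test_q_zero_gives_zero_inner_sphere(self, relax_fel3):
        assert inner_sphere_r1(relax_fel3, FieldPoint(20.0)) == 0.0

    def test_slow_exchange_limit_is_Pm_over_tauM(self, relax_fel2):
        slow = relax_fel2.updated(tauM298_s=272e-9 * 1e6)
        got = inner_sphere_r1(slow, FieldPoint(60.0))
        Pm = slow.q * 1e-3 / 55.6
        assert got == pytest.approx(Pm / slow.tauM298_s, rel=1e-3)
        # and field-independent in this limit
        assert inner_sphere_r1(slow, FieldPoint(0.01)) == pytest.approx(got, rel=1e-3)

    def test_second_sphere_r6_scaling_at_low_field(self, relax_fel3):
        base = second_sphere_r1(relax_fel3, FieldPoint(0.01))
        halved = second_sphere_r1(relax_fel3.updated(r_SS_A=relax_fel3.r_SS_A / 2), FieldPoint(0.01))
        # T1M becomes so short that the tauM_SS denominator caps the gain;
        # compare pure T1M-limited variants (tauM_SS negligible)
        fast = relax_fel3.updated(tauM_SS_s=1e-15)
        base_f = second_sphere_r1(fast, FieldPoint(0.01))
        halved_f = second_sphere_r1(fast.updated(r_SS_A=fast.r_SS_A / 2), FieldPoint(0.01))
        assert halved_f / base_f == pytest.approx(2**6, rel=0.01)
        assert halved > base  # full form still increases

    def test_outer_sphere_vanishes_for_fast_diffusion(self, relax_fel3):
        fast = relax_fel3.updated(D298_m2s=1.0)  # ~9 orders above water
        assert outer_sphere_r1(fast, FieldPoint(20.0)) < 1e-6

    def test_total_insensitive_to_closest_approach_within_reported_range(self, relax_fel1):
        vals = [
            total_r1(relax_fel1.updated(a_A=a), FieldPoint(20.0))["total"]
            for a in (3.4, 3.5, 3.6)
        ]
        assert (max(vals) - min(vals)) / min(vals) < 0.05


class TestTotalR1:
    def test_breakdown_percentages_sum_to_100(self, relax_fel2):
        comp = total_r1(relax_fel2, FieldPoint(60.0))
        assert comp["pct_IS"] + comp["pct_SS"] + comp["pct_OS"] == pytest.approx(100.0)

    def test_bis_complex_reproduces_printed_relaxivity(self, relax_fel2):
        assert total_r1(relax_fel2, FieldPoint(60.0))["total"] == pytest.approx(5.4, rel=0.15)

    def test_bis_complex_inner_sphere_share_at_3T(self, relax_fel2):
        comp = total_r1(relax_fel2, FieldPoint(120.0))
        assert comp["pct_IS"] == pytest.approx(77.0, abs=10.0)

    def test_all_mechanisms_off_gives_zero(self):
        p = RelaxParams(q=0, q_SS=0, D298_m2s=1.0)
        comp = total_r1(p, FieldPoint(20.0))
        assert comp["total"] < 1e-6

    @pytest.mark.parametrize("name,f,ref", [
        ("FeL3", 60.0, 2.8), ("FeL3", 120.0, 3.2),
        ("FeL2", 60.0, 5.4), ("FeL2", 120.0, 6.5),
        ("FeL1", 60.0, 3.4), ("FeL1", 120.0, 3.3),
    ])
    def test_profiles_pass_near_printed_values(self, name, f, ref):
        from fetiron import get_relax_params
        got = total_r1(get_relax_params(name), FieldPoint(f))["total"]
        assert got == pytest.approx(ref, rel=0.15)

    def test_components_nonnegative_on_field_temperature_grid(self, relax_fel2):
        for f in np.logspace(-2, np.log10(500), 50):
            for T in (283.0, 288.0, 298.15, 310.0):
                comp = total_r1(relax_fel2, FieldPoint(f), T)
                assert comp["IS"] >= 0 and comp["SS"] >= 0 and comp["OS"] >= 0

    def test_inner_sphere_dispersion_is_nonincreasing_at_high_field(self, relax_fel1):
        # with tau_di dominated by tau_R (electron relaxation switched off)
        # the IS term can only fall with field above the omega_S dispersion;
        # with finite T1e its field dependence adds the high-field hump
        p = relax_fel1.updated(Delta2_s2=0.0)
        freqs = np.logspace(np.log10(5), np.log10(500), 30)
        vals = [inner_sphere_r1(p, FieldPoint(f)) for f in freqs]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(vals, vals[1:]))


class TestOracleEquivalence:
    def test_fixture_sets_match_transcription_oracle(self):
        from fetiron import get_relax_params
        for name in ("FeL1", "FeL2", "FeL3"):
            p = get_relax_params(name)
            for f in (0.01, 1.0, 20.0, 60.0, 120.0, 500.0):
                for T in (283.0, 298.15, 310.0):
                    got = total_r1(p, FieldPoint(f), T)
                    want = total_r1_oracle(relax_params_to_oracle_dict(p), f, T)
                    assert got["total"] == pytest.approx(want["total"], rel=1e-10), (name, f, T)

    def test_random_parameter_draws_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = RelaxParams(
                q=int(rng.integers(0, 5)),
                r_MH_A=rng.uniform(2.5, 3.2),
                tauR298_ps=10 ** rng.uniform(1, 2.5),
                E_R=rng.uniform(5e3, 25e3),
                tauM298_s=10 ** rng.uniform(-8.5, -4.5),
                dH_M=rng.uniform(20e3, 60e3),
                Delta2_s2=10 ** rng.uniform(19.5, 21.5),
                E_Delta=rng.uniform(0, 6e3),
                tauv298_ps=rng.uniform(3, 12),
                E_v=1e3,
                q_SS=int(rng.integers(0, 6)),
                r_SS_A=rng.uniform(3.0, 4.0),
                tauR_SS298_ps=10 ** rng.uniform(1, 2),
                E_R_SS=rng.uniform(5e3, 20e3),
                D298_m2s=10 ** rng.uniform(-9.2, -8.5),
                E_D=20e3,
                a_A=rng.uniform(3.2, 4.0),
            )
            f = 10 ** rng.uniform(-2, np.log10(500))
            T = rng.uniform(278, 320)
            got = total_r1(p, FieldPoint(f), T)["total"]
            want = total_r1_oracle(relax_params_to_oracle_dict(p), f, T)["total"]
            assert got == pytest.approx(want, rel=1e-10)

    def test_nmrd_profile_matches_pointwise_evaluation(self, relax_fel2):
        freqs = np.array([0.01, 1.0, 60.0])
        prof = nmrd_profile(relax_fel2, freqs, 298.15)
        for f, v in zip(freqs, prof):
            assert v == total_r1(relax_fel2, FieldPoint(f), 298.15)["total"]
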