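"""Analytic run-length theory, validated against the Gillespie oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluidcargo import analytic as an

S_T = 4 * math.pi * 250.0**2


class TestAccessArea:
    def test_out_of_reach_is_zero(self):
        assert an.access_area_fraction(1.0e4, 250.0, 57.0, 12.5) == 0.0

    def test_whole_sphere_in_reach(self):
        """Tiny cargo with an enormous rest length: fraction → 1."""
        frac = an.access_area_fraction(30.0, 10.0, 1.0e4, 12.5)
        assert frac == pytest.approx(1.0, abs=1e-6)

    def test_monotone_decreasing_in_height(self):
        hs = np.linspace(265.0, 315.0, 8)
        fr = [an.access_area_fraction(h, 250.0, 57.0, 12.5, n_theta=4001)
              for h in hs]
        assert np.all(np.diff(fr) < 0)

    def test_monotone_increasing_in_rest_length(self):
        ls = np.linspace(40.0, 90.0, 6)
        fr = [an.access_area_fraction(300.0, 250.0, L, 12.5, n_theta=4001)
              for L in ls]
        assert np.all(np.diff(fr) > 0)

    def test_quadrature_converged(self):
        coarse = an.access_area_fraction(300.0, 250.0, 57.0, 12.5,
                                         n_theta=2001)
        fine = an.access_area_fraction(300.0, 250.0, 57.0, 12.5,
                                       n_theta=40001)
        assert coarse == pytest.approx(fine, abs=1e-4)


class TestInfluxArea:
    def test_zero_diffusion(self):
        assert an.influx_area(0.0, 10.0, 300.0, 250.0, 57.0, 12.5) == 0.0

    def test_saturates_at_complement(self):
        """d = sqrt(2Dτ) ≈ 4.5 μm ≫ πR: the band covers the sphere."""
        sa = an.access_area_fraction(300.0, 250.0, 57.0, 12.5) * S_T
        si = an.influx_area(1.0, 10.0, 300.0, 250.0, 57.0, 12.5)
        assert si == pytest.approx(S_T - sa, rel=1e-3)

    def test_monotone_in_diffusivity(self):
        vals = [an.influx_area(D, 1.0, 300.0, 250.0, 57.0, 12.5)
                for D in (1e-4, 1e-3, 1e-2)]
        assert vals[0] < vals[1] < vals[2]

    def test_band_smaller_than_complement(self):
        sa = an.access_area_fraction(300.0, 250.0, 57.0, 12.5) * S_T
        si = an.influx_area(1e-3, 1.0, 300.0, 250.0, 57.0, 12.5)
        assert 0 < si < S_T - sa


class TestAvailableMotors:
    def test_full_coverage(self):
        assert an.available_motors(16, 0.6 * S_T, 0.4 * S_T, S_T) == 16.0

    def test_single_motor(self):
        assert an.available_motors(1, 0.1, 0.5, S_T) == 1.0

    def test_rigid_minimum(self):
        na = an.available_motors(16, 0.0247 * S_T, 0.0, S_T)
        assert na == pytest.approx(1 + 15 * 0.0247)


class TestEffectiveOnRate:
    def test_no_influx_gives_pi0(self):
        assert an.effective_on_rate(5.0, 1.0, 0.0) == 5.0

    def test_vanishing_access_area(self):
        assert an.effective_on_rate(5.0, 0.0, 1.0) == 0.0
        assert an.effective_on_rate(5.0, 0.0, 0.0, S_T,
                                    variant="fixed_height") == 0.0

    def test_fixed_height_variant(self):
        assert an.effective_on_rate(
            5.0, 0.03 * S_T, S_T=S_T, variant="fixed_height"
        ) == pytest.approx(0.15)


class TestRunLengthFormula:
    def test_single_motor_collapse(self):
        assert an.run_length_formula(782.8, 1.0, 5.0, 0.79) == (
            pytest.approx(782.8 / 0.79)
        )

    def test_two_motor_expansion(self):
        v0, pi, eps = 500.0, 2.0, 0.5
        expected = v0 / (2 * pi) * ((1 + pi / eps) ** 2 - 1)
        assert an.run_length_formula(v0, 2.0, pi, eps) == (
            pytest.approx(expected, rel=1e-12)
        )

    def test_divergence_at_zero_off_rate(self):
        with pytest.raises(ZeroDivisionError):
            an.run_length_formula(500.0, 2.0, 1.0, 0.0)

    @settings(max_examples=60, deadline=None)
    @given(
        st.floats(1.1, 16.0), st.floats(0.1, 5.0), st.floats(0.05, 2.0),
        st.floats(0.01, 0.3),
    )
    def test_monotonicity(self, na, pi, eps, dpi):
        """r increases in N_a, π_ad, v0 and decreases in ε_m."""
        v0 = 500.0
        r = an.run_length_formula(v0, na, pi, eps)
        assert an.run_length_formula(v0, na + 0.5, pi, eps) > r
        assert an.run_length_formula(v0, na, pi + dpi, eps) > r
        assert an.run_length_formula(1.1 * v0, na, pi, eps) > r
        assert an.run_length_formula(v0, na, pi, eps * 1.1) < r

    @pytest.mark.parametrize("na", [1, 2, 3, 4])
    def test_matches_gillespie_oracle(self, na):
        """Central correctness property: the closed form equals the mean
        of the exact birth–death simulation for integer N_a."""
        v0, pi, eps = 700.0, 1.2, 0.6
        mean, sem = an.gillespie_run_length(v0, na, pi, eps, 4000, seed=na)
        assert abs(mean - an.run_length_formula(v0, na, pi, eps)) < 3 * sem


class TestRigidWeighted:
    def test_limits(self):
        v0, pi0, eps = 500.0, 5.0, 0.12
        lo = an.rigid_weighted_runlength(16, 1e-12, v0, pi0, eps)
        assert lo == pytest.approx(v0 / eps, rel=1e-6)
        hi = an.rigid_weighted_runlength(16, 1.0 - 1e-12, v0, pi0, eps)
        assert hi == pytest.approx(
            an.run_length_formula(v0, 16.0, pi0, eps), rel=1e-6
        )

    def test_monotone_in_access_fraction(self):
        v0, pi0, eps = 500.0, 5.0, 0.12
        vals = [an.rigid_weighted_runlength(16, p, v0, pi0, eps)
                for p in (0.01, 0.05, 0.2, 0.6)]
        assert np.all(np.diff(vals) > 0)


class TestTimescales:
    def test_tau_off_reciprocal(self):
        res = an.timescale_estimates(782.8, 782.8, 0.79, 4.0, 0.15)
        assert res["tau_off"] == pytest.approx(1 / 0.79)

    def test_na_one_infinite_binding_time(self):
        res = an.timescale_estimates(782.8, 782.8, 0.79, 1.0, 5.0)
        assert math.isinf(res["tau_bind"])
        assert not res["fluidity_sensitive"]

    @pytest.mark.parametrize(
        "N,atp,expect_sensitive",
        [
            (4, 2000.0, False),
            (4, 100.0, False),
            (4, 4.9, True),
            (16, 2000.0, True),
            (16, 100.0, True),
        ],
    )
    def test_scenario_classification(self, N, atp, expect_sensitive):
        """The five motor-number/ATP scenarios split exactly as observed:
        fluidity lengthens runs iff τ_bind < τ_off."""
        sa_frac = an.access_area_fraction(285.0, 250.0, 57.0, 12.5)
        v0 = 800.0 * atp / (44.0 + atp)
        v0_sat = 800.0 * 2000.0 / 2044.0
        # fluid limit: influx saturated
        na = an.available_motors(N, sa_frac * S_T, (1 - sa_frac) * S_T, S_T)
        pi_ad = an.effective_on_rate(5.0, sa_frac * S_T, (1 - sa_frac) * S_T)
        res = an.timescale_estimates(v0, v0_sat, 0.79, na, pi_ad)
        assert res["fluidity_sensitive"] == expect_sensitive


class TestBoundsAndEstimates:
    @pytest.fixture(scope="class")
    def result(self):
        sc = an.RunLengthScenario(N=4, v0=800 * 4.9 / 48.9)
        return an.runlength_bounds_and_estimates(
            sc, D_grid=(0.0, 1e-3, 1e-2, 1.0)
        )

    def test_ordering(self, result):
        """Lower bound ≤ every estimate ≤ upper bound for all D."""
        for key in ("est_availability", "est_height", "est_interference",
                    "est_tau_c"):
            assert np.all(result[key] >= result["lower_bound"] * (1 - 1e-6))
            assert np.all(result[key] <= result["upper_bound"] * (1 + 1e-6))

    def test_interference_gain_positive(self, result):
        """Replacing ε_m = 0.12 → 0.10 raises the estimate."""
        assert result["delta_i"] > 0

    def test_estimates_increase_with_diffusivity(self, result):
        for key in ("est_availability", "est_height", "est_interference"):
            assert np.all(np.diff(result[key]) >= -1e-9)

    def test_d_zero_reduces_to_lower_bound(self, result):
        assert result["est_availability"][0] == pytest.approx(
            result["lower_bound"], rel=1e-9
        )
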