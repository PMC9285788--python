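"""Two-community chlorophyll model: shapes, normalization, two-step tuning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phytopart as pp
from phytopart.chl import (
    NormalizedProfile,
    ProfileSkipped,
    community1,
    community2,
    empirical_p1,
    empirical_tau1,
    fit_step1,
    fit_step2,
    integrate_column,
    normalize_chl,
    partition_profile,
    total_chl_star,
)
from phytopart.config import ChlFitConfig
from phytopart.environment import OpticalContext
from conftest import TRUTH_GAUSS, TRUTH_SIGMOID


class TestCommunityShapes:
    def test_sigmoid_midpoint(self):
        assert community1(4.0, 9.0, 4.0) == pytest.approx(0.5)

    def test_sigmoid_surface_dominance_at_lower_p1_bound(self):
        # with P1 = 4.6 community 1 is just above 99% of the surface total
        assert community1(0.0, 4.6, 3.0) == pytest.approx(1 - 1 / (1 + np.exp(4.6)))
        assert community1(0.0, 4.6, 3.0) > 0.99

    def test_sigmoid_vanishes_at_depth(self):
        assert community1(1e3, 9.0, 4.0) < 1e-10

    def test_sigmoid_rejects_zero_tau1(self):
        with pytest.raises(ValueError):
            community1(1.0, 9.0, 0.0)

    @given(st.floats(4.6, 100), st.floats(0.5, 10))
    @settings(max_examples=50, deadline=None)
    def test_sigmoid_strictly_decreasing(self, p1, tau1):
        tau = np.linspace(0, 12, 200)
        b1 = community1(tau, p1, tau1)
        assert np.all(np.diff(b1) <= 0)
        # strictly decreasing wherever neither saturation tail has rounded off
        interior = (b1 > 1e-12) & (b1 < 1 - 1e-12)
        assert np.all(np.diff(b1[interior]) < 0)
        assert np.all((b1 >= 0) & (b1 <= 1))

    def test_gaussian_peak_and_symmetry(self):
        assert community2(5.0, 2.0, 5.0, 1.0) == pytest.approx(2.0)
        assert community2(4.0, 2.0, 5.0, 1.0) == pytest.approx(community2(6.0, 2.0, 5.0, 1.0))
        assert community2(4.0, 2.0, 5.0, 1.0) == pytest.approx(2.0 / np.e)

    def test_gaussian_surface_suppression_at_constraint(self):
        # B2m* = 80 with tau2 = 3 sigma leaves < 1% of the surface total
        val = community2(0.0, 80.0, 3.0, 1.0)
        assert val == pytest.approx(80 * np.exp(-9), rel=1e-12)
        assert val < 0.01

    def test_gaussian_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            community2(1.0, 2.0, 5.0, 0.0)
        with pytest.raises(ValueError):
            community2(1.0, -1.0, 5.0, 1.0)

    @given(
        st.floats(4.6, 100), st.floats(0.5, 10), st.floats(0, 80),
        st.floats(0.1, 3), st.floats(0, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_total_is_exact_sum(self, p1, tau1, b2m, sigma, delta):
        tau2 = 3 * sigma + delta
        tau = np.linspace(0, 10, 50)
        params = dict(p1=p1, tau1=tau1, b2m_star=b2m, tau2=tau2, sigma=sigma)
        total = total_chl_star(tau, params)
        np.testing.assert_array_equal(
            total, community1(tau, p1, tau1) + community2(tau, b2m, tau2, sigma)
        )

    def test_one_community_mode_is_sigmoid_alone(self):
        tau = np.linspace(0, 10, 50)
        params = dict(p1=9.0, tau1=4.0)
        np.testing.assert_array_equal(
            total_chl_star(tau, params, "one_community"), community1(tau, 9.0, 4.0)
        )

    def test_surface_total_in_unit_band_over_admissible_box(self):
        # grid search over the admissible parameter box: total at tau=0
        # stays within 1% of unity
        for p1 in np.linspace(4.6, 100, 12):
            for sigma in np.linspace(0.1, 3, 8):
                for b2m in np.linspace(0, 80, 9):
                    params = dict(p1=p1, tau1=2.0, b2m_star=b2m,
                                  tau2=3 * sigma, sigma=sigma)
                    total = total_chl_star(0.0, params)
                    assert 0.99 < total < 1.01


class TestNormalize:
    def _record(self, chl, kd=0.05, zm=80.0, depth=None):
        depth = np.linspace(0, 250, chl.size) if depth is None else depth
        rec = pp.make_profile(
            dict(mode="one_community", **TRUTH_SIGMOID), kd=kd, b_s=0.3,
            b_bp_s=1.75e-3, time="2016-01-05T08:00", zm=zm, depth=depth,
            noise_chl=0, noise_bbp=0, noise_par=0, rng=np.random.default_rng(0),
        )
        rec.chl = np.asarray(chl, dtype=float)
        return rec

    def _ctx(self, kd=0.05, zm=80.0):
        return OpticalContext(kd=kd, kd_source="fitted", b_s=np.nan, b_s10=0.3,
                              b_bp_s=1.7e-3, z_p=4.6 / kd, z_m=zm, strat_index=1e-5)

    def test_constant_profile_normalizes_to_one(self):
        rec = self._record(np.full(50, 0.5))
        norm = normalize_chl(rec, self._ctx())
        assert norm.b_s == pytest.approx(0.5)
        np.testing.assert_allclose(norm.b_star, 1.0)

    def test_surface_median_drops_unrealistic_values(self):
        # depths 0/8/16 m are all within the first optical depth (20 m);
        # the 0.005 sample is below the 0.01 floor -> median of {0.3, 0.4}
        chl = np.concatenate([[0.005, 0.3, 0.4], np.full(47, 0.2)])
        depth = np.linspace(0, 392, 50)
        rec = self._record(chl, depth=depth)
        norm = normalize_chl(rec, self._ctx())
        assert norm.b_s == pytest.approx(0.35)

    def test_truncation_below_9p2_when_shallow_mixed_layer(self):
        # Z_m Kd = 3 < 9.2, profile reaching tau = 12.5 -> fitted data < 9.2
        rec = self._record(np.full(100, 0.3), zm=60.0)
        norm = normalize_chl(rec, self._ctx(zm=60.0))
        assert norm.tau.max() < 9.2

    def test_full_profile_kept_when_deeply_mixed(self):
        rec = self._record(np.full(100, 0.3), zm=200.0)
        norm = normalize_chl(rec, self._ctx(zm=200.0))
        assert norm.tau.max() == pytest.approx(250 * 0.05)

    def test_too_few_points_skipped(self):
        rec = self._record(np.full(5, 0.3), depth=np.linspace(0, 100, 5))
        with pytest.raises(ProfileSkipped, match="usable samples"):
            normalize_chl(rec, self._ctx())

    def test_no_surface_samples_skipped(self):
        chl = np.full(50, 0.3)
        chl[:5] = np.nan  # first optical depth is 20 m = first 4 samples
        depth = np.linspace(0, 245, 50)
        rec = self._record(chl, depth=depth)
        with pytest.raises(ProfileSkipped, match="first optical depth"):
            normalize_chl(rec, self._ctx())


class TestEmpiricalRelations:
    def test_tau1_intercept_and_slope(self):
        assert empirical_tau1(0.0) == pytest.approx(2.29)
        assert empirical_tau1(10.0) == pytest.approx(8.49)

    def test_p1_from_tau1(self):
        assert empirical_p1(2.29) == pytest.approx(10 ** (0.08 * 2.29 + 0.66), rel=1e-12)
        assert empirical_p1(2.29) == pytest.approx(6.97, abs=0.01)

    def test_p1_clipped_to_admissible_box(self):
        assert empirical_p1(100.0) == 100.0

    def test_negative_zmkd_rejected(self):
        with pytest.raises(ValueError):
            empirical_tau1(-1.0)


class TestStepFits:
    def test_step1_noiseless_recovery(self, tau_grid, context, fast_chl_config):
        b = community1(tau_grid, **TRUTH_SIGMOID)
        fit = fit_step1(NormalizedProfile(tau_grid, b, 0.3), context, fast_chl_config)
        assert fit.params["p1"] == pytest.approx(TRUTH_SIGMOID["p1"], rel=1e-3)
        assert fit.params["tau1"] == pytest.approx(TRUTH_SIGMOID["tau1"], rel=1e-3)
        assert fit.r2 > 0.999

    def test_step1_noisy_ci_covers_truth(self, tau_grid, context):
        rng = np.random.default_rng(5)
        cfg = ChlFitConfig(bootstrap_n=200)
        b = community1(tau_grid, **TRUTH_SIGMOID) * (1 + 0.05 * rng.standard_normal(50))
        fit = fit_step1(NormalizedProfile(tau_grid, b, 0.3), context, cfg, rng)
        for p, truth in TRUTH_SIGMOID.items():
            lo, hi = fit.ci[p]
            assert lo <= fit.medians[p] <= hi
            assert lo <= truth <= hi

    def test_step1_strong_dcm_fails_variance_gate(self, tau_grid, context, fast_chl_config):
        b = total_chl_star(tau_grid, dict(**TRUTH_SIGMOID, b2m_star=3.0, tau2=5.0, sigma=1.0))
        fit = fit_step1(NormalizedProfile(tau_grid, b, 0.3), context, fast_chl_config)
        assert fit.r2 < 0.9

    def test_step2_noiseless_recovery_with_truth_fixed(self, tau_grid, fast_chl_config):
        b = total_chl_star(tau_grid, dict(**TRUTH_SIGMOID, **TRUTH_GAUSS))
        fit = fit_step2(NormalizedProfile(tau_grid, b, 0.3),
                        TRUTH_SIGMOID["p1"], TRUTH_SIGMOID["tau1"], fast_chl_config)
        for p, truth in TRUTH_GAUSS.items():
            assert fit.params[p] == pytest.approx(truth, rel=1e-3)

    def test_step2_constraint_always_satisfied(self, tau_grid, fast_chl_config):
        # even with a shallow-peak profile the returned tau2 >= 3 sigma
        rng = np.random.default_rng(9)
        for _ in range(10):
            b = total_chl_star(
                tau_grid, dict(**TRUTH_SIGMOID, b2m_star=1.5, tau2=3.2, sigma=1.05)
            ) * (1 + 0.05 * rng.standard_normal(50))
            fit = fit_step2(NormalizedProfile(tau_grid, b, 0.3), 9.0, 4.0,
                            fast_chl_config, rng)
            assert fit.params["tau2"] >= 3 * fit.params["sigma"] - 1e-9


class TestPartitionProfile:
    def test_winter_mixed_profile_is_one_community(self, fast_chl_config):
        rec = pp.make_profile(
            dict(mode="one_community", p1=27.0, tau1=9.7), kd=0.067, b_s=0.5,
            b_bp_s=1.75e-3, time="2016-01-17T08:00", zm=180.0, t_surf=24.0,
            noise_chl=0.03, noise_bbp=0, noise_par=0, rng=np.random.default_rng(2),
        )
        ctx = pp.compute_context(rec)
        fit = partition_profile(rec, ctx, fast_chl_config)
        assert fit.mode == "one_community"

    def test_summer_dcm_profile_is_two_community(self, fast_chl_config):
        rec = pp.make_profile(
            dict(mode="two_community", p1=7.8, tau1=2.9, b2m_star=3.0,
                 tau2=5.2, sigma=1.3), kd=0.052, b_s=0.08, b_bp_s=1.75e-3,
            time="2016-07-13T08:00", zm=20.0, t_surf=30.0,
            noise_chl=0.03, noise_bbp=0, noise_par=0, rng=np.random.default_rng(3),
        )
        ctx = pp.compute_context(rec)
        fit = partition_profile(rec, ctx, fast_chl_config)
        assert fit.mode == "two_community"
        assert fit.tau2 >= 3 * fit.sigma - 1e-9

    def test_short_profile_skipped(self, fast_chl_config):
        rec = pp.make_profile(
            dict(mode="one_community", **TRUTH_SIGMOID), kd=0.05, b_s=0.3,
            b_bp_s=1.75e-3, time="2016-01-05T08:00", zm=50.0,
            depth=np.linspace(0, 100, 5), noise_chl=0, noise_bbp=0, noise_par=0,
            rng=np.random.default_rng(0),
        )
        ctx = pp.compute_context(rec)
        with pytest.raises(ProfileSkipped):
            partition_profile(rec, ctx, fast_chl_config)


class TestIntegrateColumn:
    def test_constant_profile(self):
        z = np.linspace(0, 100, 51)
        assert integrate_column(np.full(51, 2.0), z, 100.0) == pytest.approx(200.0)

    def test_linear_profile_exact(self):
        z = np.linspace(0, 100, 51)
        assert integrate_column(0.1 * z, z, 100.0) == pytest.approx(0.05 * 100**2)

    def test_interpolates_to_limit(self):
        z = np.array([0.0, 10.0, 20.0])
        v = np.array([1.0, 1.0, 1.0])
        assert integrate_column(v, z, 15.0) == pytest.approx(15.0)

    def test_random_profile_matches_fine_quadrature(self):
        rng = np.random.default_rng(17)
        z = np.sort(rng.uniform(0, 200, 80))
        v = np.abs(rng.standard_normal(80)) + 0.1
        zf = np.linspace(z[0], 150.0, 1000)
        oracle = np.trapezoid(np.interp(zf, z, v), zf)
        assert integrate_column(v, z, 150.0) == pytest.approx(oracle, rel=0.01)

    def test_limit_above_shallowest_sample_fails(self):
        with pytest.raises(ValueError, match="shallowest"):
            integrate_column(np.array([1.0, 1.0]), np.array([50.0, 100.0]), 20.0)
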