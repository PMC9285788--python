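"""Optical and physical context derivations."""

import numpy as np
import pandas as pd
import pytest

from phytopart import environment as env
from phytopart.environment import (
    KdFitError,
    NightProfileError,
    brunt_vaisala,
    daily_par,
    density_profile,
    euphotic_depth,
    fit_kd,
    kd_from_chl,
    mean_light,
    mixed_layer_depth,
    optical_depth,
    stratification_index,
)


class TestKd:
    def test_exact_exponential_recovered(self):
        z = np.linspace(0, 100, 40)
        assert fit_kd(z, 100 * np.exp(-0.05 * z)) == pytest.approx(0.05, rel=1e-12)

    def test_constant_par_rejected(self):
        z = np.linspace(0, 100, 20)
        with pytest.raises(KdFitError, match="non-positive"):
            fit_kd(z, np.full(20, 50.0))

    def test_too_few_points_signals_fallback(self):
        with pytest.raises(KdFitError, match="need 4"):
            fit_kd(np.array([0, 10, 20.0]), np.array([100, 60, 40.0]))

    def test_noisy_exponential_within_5pct(self):
        rng = np.random.default_rng(11)
        z = np.linspace(0, 100, 50)
        par = 100 * np.exp(-0.05 * z) * np.exp(0.05 * rng.standard_normal(50))
        assert fit_kd(z, par) == pytest.approx(0.05, rel=0.05)

    def test_samples_below_100m_ignored(self):
        z = np.linspace(0, 300, 100)
        par = 100 * np.exp(-0.05 * z)
        par[z > 100] = 1e-3  # corrupted deep values must not matter
        assert fit_kd(z, par) == pytest.approx(0.05, rel=1e-10)

    @pytest.mark.parametrize("bs10, expected", [(0.0, 0.049), (1.0, 0.085), (2.0, 0.121)])
    def test_empirical_relation(self, bs10, expected):
        assert kd_from_chl(bs10) == pytest.approx(expected, abs=1e-12)

    def test_empirical_rejects_negative(self):
        with pytest.raises(ValueError):
            kd_from_chl(-0.1)


class TestOpticalDepths:
    @pytest.mark.parametrize("kd, zp", [(0.046, 100.0), (0.092, 50.0)])
    def test_euphotic_depth(self, kd, zp):
        assert euphotic_depth(kd) == pytest.approx(zp)

    def test_clearest_case_intercept(self):
        assert euphotic_depth(0.049) == pytest.approx(93.88, abs=0.01)

    def test_euphotic_depth_requires_positive_kd(self):
        with pytest.raises(ValueError):
            euphotic_depth(0.0)

    def test_tau_at_euphotic_and_one_and_a_half_euphotic(self):
        kd = 0.057
        zp = euphotic_depth(kd)
        assert optical_depth(zp, kd) == pytest.approx(4.6)
        assert optical_depth(1.5 * zp, kd) == pytest.approx(6.9)
        assert optical_depth(0.0, kd) == 0.0


class TestDailyPar:
    def test_equator_equinox_day_length(self):
        day_length, _ = env._solar_geometry("2016-03-20T12:00", 0.0, 0.0)
        assert day_length == pytest.approx(12.0, abs=0.2)

    def test_noon_measurement_sinusoid_identity(self):
        # at local noon sin(pi t/D) = 1, so E_noon = E and integral = 2D/pi * E
        day_length, _ = env._solar_geometry("2016-06-21T12:00", 25.0, 0.0)
        e = 1500.0
        got = daily_par(e, "2016-06-21T12:00", 25.0, 0.0)
        assert got == pytest.approx(2 * day_length * 3600 * e / np.pi * 1e-6, rel=1e-9)

    def test_independent_of_measurement_time(self):
        # sample the same true sinusoid at several times of day: identical integrals
        lat, lon = 25.0, 0.0
        day_length, _ = env._solar_geometry("2016-06-21T12:00", lat, lon)
        sunrise_h = 12.0 - day_length / 2.0
        e_noon = 1800.0
        integrals = []
        for frac in (0.25, 0.5, 0.75):
            t = pd.Timestamp("2016-06-21") + pd.Timedelta(
                seconds=round((sunrise_h + frac * day_length) * 3600)
            )
            e = e_noon * np.sin(np.pi * frac)
            integrals.append(daily_par(e, t, lat, lon))
        # quadrature oracle for the sinusoid
        tt = np.linspace(0, day_length * 3600, 200001)
        oracle = np.trapezoid(e_noon * np.sin(np.pi * tt / (day_length * 3600)), tt) * 1e-6
        np.testing.assert_allclose(integrals, oracle, rtol=1e-4)

    def test_night_measurement_disregarded(self):
        with pytest.raises(NightProfileError):
            daily_par(1.0, "2016-06-21T01:00", 25.0, 0.0)


class TestDensityAndStratification:
    def test_reference_value(self):
        assert density_profile([10.0], [35.0], [0.0])[0] == pytest.approx(1026.95, abs=0.01)

    def test_fresh_warm_lighter_than_salty_cold(self):
        fresh_warm = density_profile([28.0], [34.0], [0.0])[0]
        salty_cold = density_profile([10.0], [39.0], [0.0])[0]
        assert fresh_warm < salty_cold

    def test_out_of_range_masked_with_warning(self):
        with pytest.warns(UserWarning, match="masked"):
            rho = density_profile([10.0, 10.0], [35.0, 60.0], [0.0, 0.0])
        assert np.isnan(rho[1]) and np.isfinite(rho[0])

    def test_uniform_density_gives_zero_n2(self):
        z = np.linspace(0, 200, 50)
        _, n2 = brunt_vaisala(np.full(50, 1026.0), z)
        np.testing.assert_allclose(n2, 0.0)

    def test_linear_density_closed_form(self):
        z = np.linspace(0, 200, 101)
        rho = 1025.0 + 0.01 * z
        _, n2 = brunt_vaisala(rho, z)
        np.testing.assert_allclose(n2, 9.81 * 0.01 / (1025.0 + 0.01 * 100), rtol=0.01)

    def test_two_layer_peak_at_interface(self):
        z = np.linspace(0, 200, 201)
        rho = np.where(z < 100, 1025.0, 1027.0)
        z_mid, n2 = brunt_vaisala(rho, z)
        assert abs(z_mid[np.argmax(n2)] - 100.0) <= 1.0

    def test_single_depth_fails(self):
        with pytest.raises(ValueError):
            brunt_vaisala(np.array([1025.0]), np.array([10.0]))

    def test_strat_index_constant(self):
        tau = np.linspace(0.1, 10, 100)
        assert stratification_index(np.full(100, 3e-5), tau) == pytest.approx(3e-5)

    def test_strat_index_ignores_deep_signal(self):
        tau = np.linspace(0.1, 12, 120)
        n2 = np.where(tau > 6.95, 1e-3, 0.0)
        assert stratification_index(n2, tau) == pytest.approx(0.0, abs=1e-7)

    def test_strat_index_matches_quadrature_and_resampling(self):
        rng = np.random.default_rng(3)
        tau = np.linspace(0.05, 9.0, 60)
        n2 = 1e-5 * (1 + 0.5 * np.sin(tau)) + 1e-6 * rng.standard_normal(60)
        coarse = stratification_index(n2, tau)
        tau_f = np.linspace(0.05, 9.0, 6000)
        fine = stratification_index(np.interp(tau_f, tau, n2), tau_f)
        assert coarse == pytest.approx(fine, rel=0.01)


class TestMixedLayerDepth:
    def test_two_layer_interface(self):
        z = np.linspace(0, 200, 201)
        t = np.where(z < 50, 28.0, 22.0)
        for method in ("threshold", "holte_talley_temp"):
            mld = mixed_layer_depth(t, z, method=method)
            # interface sits between grid cells 49 and 50
            assert mld.zm == pytest.approx(49.5, abs=0.51)

    def test_isothermal_flagged_fully_mixed(self):
        z = np.linspace(0, 500, 100)
        mld = mixed_layer_depth(np.full(100, 22.0), z)
        assert mld.fully_mixed
        assert mld.zm == pytest.approx(500.0)

    def test_smooth_thermocline_methods_agree_within_10m(self):
        z = np.linspace(0, 300, 301)
        t = 22.0 + 6.0 / (1 + np.exp((z - 60) / 10.0))
        ht = mixed_layer_depth(t, z, method="holte_talley_temp")
        thr = mixed_layer_depth(t, z, method="threshold")
        assert abs(ht.zm - thr.zm) <= 10.0

    def test_too_shallow_profile_fails(self):
        with pytest.raises(ValueError, match="10 m"):
            mixed_layer_depth(np.array([28.0, 27.9]), np.array([0.0, 5.0]))


class TestMeanLight:
    def test_small_kd_limit_approaches_surface_value(self):
        assert mean_light(30.0, 1e-9, 0.0, 50.0) == pytest.approx(30.0, rel=1e-6)

    def test_euphotic_layer_closed_form(self):
        kd = 0.05
        zp = 4.6 / kd
        expected = 30.0 * (1 - np.exp(-4.6)) / 4.6
        assert mean_light(30.0, kd, 0.0, zp) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_layer_point_value(self):
        assert mean_light(30.0, 0.05, 40.0, 40.0) == pytest.approx(30.0 * np.exp(-2.0))

    def test_matches_quadrature(self):
        kd, top, bot = 0.07, 15.0, 120.0
        z = np.linspace(top, bot, 100001)
        oracle = np.trapezoid(30.0 * np.exp(-kd * z), z) / (bot - top)
        assert mean_light(30.0, kd, top, bot) == pytest.approx(oracle, rel=1e-3)


class TestComputeContext:
    def test_zp_kd_identity_and_fitted_kd(self, noiseless_profile):
        ctx = env.compute_context(noiseless_profile)
        assert ctx.z_p * ctx.kd == pytest.approx(4.6, abs=1e-12)
        assert ctx.kd_source == "fitted"
        assert ctx.kd == pytest.approx(0.05, rel=1e-6)
        # surface values are medians over the first optical depth, slightly
        # below the exact z=0 values of the generating model
        assert ctx.b_s == pytest.approx(0.3, rel=1e-3)
        assert ctx.b_bp_s == pytest.approx(1.75e-3, rel=1e-3)
        assert ctx.par_ml is not None and ctx.par_ml > 0

    def test_empirical_fallback_without_par(self, noiseless_profile):
        noiseless_profile.par = None
        ctx = env.compute_context(noiseless_profile)
        assert ctx.kd_source == "empirical"
        assert ctx.kd == pytest.approx(0.036 * ctx.b_s10 + 0.049, rel=1e-12)
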