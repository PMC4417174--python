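import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from etsdyn.bend import (BendMobilityModel, MobilityProfile, compare_profiles,
                         confidence_band, fit_profile, k_from_ends, predict_rf)
from etsdyn.exceptions import FittingError, ValidationError

from conftest import make_noisefree_profile, make_noisy_profile


def rod_kink_oracle(x, theta_deg):
    """Squared end-to-end distance of a unit rod kinked by theta at fraction x,
    by explicit 2-D vector geometry (independent of the model formula)."""
    t = np.deg2rad(theta_deg)
    u = np.array([1.0, 0.0])
    v = np.array([np.cos(t), np.sin(t)])
    end = x * u + (1.0 - x) * v
    return float(end @ end)


class TestPredictRf:
    def test_ends_equal_K_for_any_angle(self):
        for theta in (0.0, 33.0, 90.0, 179.0):
            assert predict_rf(0.0, 0.90, theta) == pytest.approx(0.90)
            assert predict_rf(1.0, 0.90, theta) == pytest.approx(0.90)

    def test_straight_dna_is_identity(self):
        assert predict_rf(0.5, 1.0, 0.0) == pytest.approx(1.0)

    def test_right_angle_halves_midpoint_mobility(self):
        assert predict_rf(0.5, 1.0, 90.0) == pytest.approx(0.5)

    def test_matches_rod_geometry_oracle(self):
        assert predict_rf(0.25, 1.0, 60.0) == pytest.approx(0.8125)
        for x in (0.1, 0.25, 0.4, 0.5, 0.77):
            for theta in (15.0, 60.0, 120.0, 175.0):
                assert predict_rf(x, 1.0, theta) == pytest.approx(
                    rod_kink_oracle(x, theta), abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(x=st.floats(0.0, 1.0), K=st.floats(0.1, 1.5),
           theta=st.floats(0.0, 179.9))
    def test_mirror_symmetry(self, x, K, theta):
        assert predict_rf(x, K, theta) == pytest.approx(
            predict_rf(1.0 - x, K, theta), rel=1e-12)

    def test_monotone_nonincreasing_in_theta_at_interior_x(self):
        thetas = np.linspace(0.0, 179.0, 50)
        for x in (0.2, 0.5, 0.8):
            vals = [predict_rf(x, 1.0, t) for t in thetas]
            assert np.all(np.diff(vals) < 0)
        # equality only at the ends
        ends = [predict_rf(0.0, 1.0, t) for t in thetas]
        assert np.ptp(ends) == 0.0

    def test_parameter_validation(self):
        with pytest.raises(ValidationError):
            predict_rf(0.5, 1.0, 180.0)
        with pytest.raises(ValidationError):
            predict_rf(0.5, -1.0, 30.0)
        with pytest.raises(ValidationError):
            predict_rf(1.2, 1.0, 30.0)


class TestFitProfile:
    @pytest.mark.parametrize("K, theta", [(0.95, 50.0), (0.85, 80.0), (1.05, 20.0)])
    def test_noisefree_recovery(self, x11, K, theta):
        res = fit_profile(make_noisefree_profile(x11, K, theta))
        assert res.K == pytest.approx(K, rel=1e-6)
        assert res.theta_deg == pytest.approx(theta, rel=1e-6)
        assert res.rss == pytest.approx(0.0, abs=1e-16)
        assert res.df_resid == 9

    def test_flat_profile_hits_zero_angle_boundary(self, x11):
        prof = MobilityProfile(x11, np.full_like(x11, 0.9), np.zeros_like(x11),
                               np.ones_like(x11, dtype=int), "flat")
        res = fit_profile(prof)
        assert res.K == pytest.approx(0.9, rel=1e-9)
        assert res.theta_deg == pytest.approx(0.0, abs=1e-6)

    def test_monte_carlo_ci_coverage(self, x11):
        """Delta-method 95% CIs cover the generating (K, theta) in >= 90%
        of 200 simulated quadruplicate experiments."""
        hits = 0
        for seed in range(200):
            prof = make_noisy_profile(x11, 0.93, 70.0, se=0.005, n_rep=4, seed=seed)
            ci = fit_profile(prof).conf_int()
            if ci[0, 0] <= 0.93 <= ci[0, 1] and ci[1, 0] <= 70.0 <= ci[1, 1]:
                hits += 1
        assert hits >= 180

    def test_profile_likelihood_ci_brackets_estimate(self, x11):
        prof = make_noisy_profile(x11, 0.93, 70.0, seed=5)
        res = fit_profile(prof)
        ci = res.conf_int(method="profile")
        assert ci[0, 0] < res.K < ci[0, 1]
        assert ci[1, 0] < res.theta_deg < ci[1, 1]
        # comparable in width to the delta-method limits
        delta = res.conf_int()
        assert np.allclose(ci, delta, rtol=0.5, atol=1.0)

    def test_weighted_and_unweighted_agree_on_uniform_se(self, x11):
        rng = np.random.default_rng(3)
        rf = predict_rf(x11, 0.9, 55.0) + rng.normal(0, 0.005, len(x11))
        wt = fit_profile(MobilityProfile(x11, rf, np.full_like(x11, 0.005),
                                         np.full(len(x11), 4), "w"))
        unwt = fit_profile(MobilityProfile(x11, rf, np.zeros_like(x11),
                                           np.full(len(x11), 4), "u"))
        assert wt.params == pytest.approx(unwt.params, rel=1e-8)

    def test_sparse_profile_warns_but_fits(self):
        x = np.array([0.4, 0.45, 0.5, 0.55])  # no terminal coverage
        prof = MobilityProfile(x, predict_rf(x, 0.9, 60.0), np.zeros_like(x),
                               np.ones_like(x, dtype=int), "narrow")
        with pytest.warns(UserWarning, match="identif"):
            fit_profile(prof)

    def test_too_few_points_rejected(self):
        prof = MobilityProfile([0.1, 0.9], [0.9, 0.9], [0.0, 0.0], [1, 1], "2pt")
        with pytest.warns(UserWarning):
            with pytest.raises(FittingError):
                fit_profile(prof)


class TestConfidenceBand:
    def test_zero_covariance_collapses_band(self, x11, noisefree_profile):
        res = fit_profile(noisefree_profile)
        res.cov_params = np.zeros((2, 2))
        res._singular = False
        band = res.conf_band(x11)
        assert band["lower"].to_numpy() == pytest.approx(band["rf_fit"].to_numpy())
        assert band["upper"].to_numpy() == pytest.approx(band["rf_fit"].to_numpy())

    def test_band_width_at_ends_set_by_var_K_only(self, x11):
        from scipy import stats
        res = fit_profile(make_noisy_profile(x11, 0.95, 50.0, seed=1))
        band = res.conf_band(np.array([0.0]))
        half = float(band["upper"].iloc[0] - band["rf_fit"].iloc[0])
        tcrit = stats.t.ppf(0.975, res.df_resid)
        assert half == pytest.approx(tcrit * res.bse[0], rel=1e-9)
        # numerically: inflating var(theta) alone leaves the x=0 width unchanged
        res.cov_params = res.cov_params.copy()
        res.cov_params[1, 1] *= 100.0
        band2 = res.conf_band(np.array([0.0]))
        assert float(band2["upper"].iloc[0] - band2["rf_fit"].iloc[0]) == (
            pytest.approx(half, rel=1e-9))

    def test_band_symmetric_under_mirror(self, x11):
        res = fit_profile(make_noisy_profile(x11, 0.9, 60.0, seed=2))
        grid = np.linspace(0.0, 1.0, 21)
        band = confidence_band(res, grid)
        width = (band["upper"] - band["lower"]).to_numpy()
        assert width == pytest.approx(width[::-1], rel=1e-9)

    def test_singular_covariance_raises(self, x11, noisefree_profile):
        res = fit_profile(noisefree_profile)
        res._singular = True
        with pytest.raises(FittingError):
            res.conf_band(x11)


class TestKFromEnds:
    def test_identity_with_fitted_K(self, x11):
        res = fit_profile(make_noisy_profile(x11, 0.88, 45.0, seed=7))
        assert k_from_ends(res) == res.K

    def test_theta_does_not_move_end_value(self, x11):
        a = fit_profile(make_noisefree_profile(x11, 0.9, 30.0))
        b = fit_profile(make_noisefree_profile(x11, 0.9, 120.0))
        assert k_from_ends(a) == pytest.approx(k_from_ends(b), rel=1e-9)

    def test_K_shift_moves_end_value_by_same_amount(self, x11):
        a = fit_profile(make_noisefree_profile(x11, 0.90, 60.0))
        b = fit_profile(make_noisefree_profile(x11, 0.85, 60.0))
        assert k_from_ends(a) - k_from_ends(b) == pytest.approx(0.05, abs=1e-8)


def brute_force_f_stat(a, b):
    """F statistic recomputed from independently minimised RSS values
    (Nelder-Mead on the raw weighted sums of squares)."""
    def rss_fn(profile):
        w = 1.0 / profile.rf_se**2 if np.all(profile.rf_se > 0) else (
            np.ones_like(profile.rf_se))

        def f(p):
            K, theta = p
            if K <= 0 or not (0 <= theta < 180):
                return 1e12
            model = K * (1 - 2 * profile.x * (1 - profile.x)
                         * (1 - np.cos(np.deg2rad(theta))))
            return float(np.sum(w * (profile.rf_mean - model) ** 2))
        return f

    fa, fb = rss_fn(a), rss_fn(b)
    opts = {"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000}
    ra = optimize.minimize(fa, [0.9, 60.0], method="Nelder-Mead", options=opts)
    rb = optimize.minimize(fb, [0.9, 60.0], method="Nelder-Mead", options=opts)
    rg = optimize.minimize(lambda p: fa(p) + fb(p), [0.9, 60.0],
                           method="Nelder-Mead", options=opts)
    rss_sep = ra.fun + rb.fun
    df_sep = len(a) + len(b) - 4
    return ((rg.fun - rss_sep) / 2.0) / (rss_sep / df_sep)


class TestCompareProfiles:
    def test_identical_profiles_are_indistinguishable(self, x11):
        prof = make_noisy_profile(x11, 0.9, 60.0, seed=4)
        cmp = compare_profiles(prof, prof)
        assert cmp.f_stat == pytest.approx(0.0, abs=1e-6)
        assert cmp.p_value == pytest.approx(1.0, abs=1e-6)
        assert cmp.verdict == "indistinguishable"

    def test_distinct_parameters_detected_and_f_matches_brute_force(self, x11):
        a = make_noisy_profile(x11, 0.92, 40.0, seed=11, label="a")
        b = make_noisy_profile(x11, 0.85, 80.0, seed=12, label="b")
        cmp = compare_profiles(a, b)
        assert cmp.p_value < 1e-3
        assert cmp.verdict == "distinguishable"
        assert cmp.f_stat == pytest.approx(brute_force_f_stat(a, b), rel=1e-4)
        assert cmp.rss_global >= cmp.rss_separate
        assert cmp.df_separate == 18

    def test_profiles_need_not_share_x_grid(self):
        xa = np.linspace(0.05, 0.95, 11)
        xb = np.linspace(0.08, 0.92, 9)
        a = make_noisy_profile(xa, 0.9, 60.0, seed=1)
        b = make_noisy_profile(xb, 0.9, 60.0, seed=2)
        cmp = compare_profiles(a, b)
        assert 0.0 <= cmp.p_value <= 1.0

    def test_p_floor_printing(self, x11):
        a = make_noisy_profile(x11, 0.92, 40.0, seed=11)
        b = make_noisy_profile(x11, 0.85, 80.0, seed=12)
        assert compare_profiles(a, b).format_p() == "<1e-05"
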