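import numpy as np
import pytest

import csfosmo as c
from csfosmo.secretion import SecretionError


def ols_normal_equations(x, y):
    """Brute-force OLS via the normal equations, as an independent oracle."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return beta[1], beta[0], r2


class TestVpFromDye:
    def test_published_mean_rate_from_dilution_ratio(self):
        # ri = 9, Ci/Co = 1.756 inverts to the mean rate 6.8 ul/min
        assert c.vp_from_dye(9.0, 1.756, 1.0) == pytest.approx(6.8, abs=0.01)

    @pytest.mark.parametrize(
        "ri, ci, co, expected", [(9.0, 2.0, 1.0, 9.0), (9.0, 1.0, 1.0, 0.0)]
    )
    def test_hand_arithmetic(self, ri, ci, co, expected):
        assert c.vp_from_dye(ri, ci, co) == expected

    def test_absorption_returns_negative(self):
        assert c.vp_from_dye(9.0, 1.0, 2.0) < 0

    def test_nonpositive_outflow_rejected(self):
        with pytest.raises(SecretionError):
            c.vp_from_dye(9.0, 1.0, 0.0)


class TestWindowedVp:
    def test_noiseless_series_recovers_truth_exactly(self):
        series = c.gen_perfusion(true_vp=6.8, noise_cv=0.0, seed=None)
        est = c.windowed_vp(series, c.BASELINE_WINDOW)
        assert est.vp_ul_min == pytest.approx(6.8, rel=1e-12)
        assert est.se == pytest.approx(0.0, abs=1e-10)

    def test_window_outside_series_errors_with_bounds(self):
        series = c.gen_perfusion(duration_min=60.0, seed=0)
        with pytest.raises(SecretionError, match=r"\[200.0, 220.0\]"):
            c.windowed_vp(series, (200.0, 220.0))

    def test_windowed_mean_equals_pointwise_mean(self):
        series = c.gen_perfusion(true_vp=6.8, noise_cv=0.05, seed=3)
        est = c.windowed_vp(series, c.BASELINE_WINDOW)
        mask = (series.time_min >= 50) & (series.time_min <= 65)
        pointwise = c.vp_from_dye(
            9.0, series.inflow_fluor[mask], series.outflow_fluor[mask]
        )
        assert est.vp_ul_min == pytest.approx(float(np.mean(pointwise)), rel=1e-12)

    def test_round_trip_unbiased_with_honest_coverage(self):
        # the window holds only 3 fractions, so the per-run SE estimate
        # has 2 df; calibration is judged against the true sampling SE
        errors, ses = [], []
        for seed in range(200):
            series = c.gen_perfusion(true_vp=6.8, noise_cv=0.03, seed=seed)
            est = c.windowed_vp(series, c.BASELINE_WINDOW)
            errors.append(est.vp_ul_min - 6.8)
            ses.append(est.se)
        errors = np.asarray(errors)
        sampling_se = errors.std(ddof=1)
        assert abs(errors.mean()) < 0.5 * sampling_se
        covered = np.mean(np.abs(errors) <= 2 * sampling_se)
        assert covered >= 0.90
        # the per-run SE estimate is itself unbiased for the sampling SE
        assert np.mean(ses) == pytest.approx(sampling_se, rel=0.25)


class TestPercentInhibition:
    @pytest.mark.parametrize(
        "base, treat, expected",
        [
            (6.8, 4.352, 36.0),   # NKCC1-blocker scale reduction
            (6.8, 6.8, 0.0),
            (0.40, 0.15, 62.5),   # efflux rate-constant reduction (~60%)
        ],
    )
    def test_values(self, base, treat, expected):
        assert c.percent_inhibition(base, treat) == pytest.approx(expected, abs=0.01)

    def test_accepts_estimates(self):
        base = c.SecretionEstimate(6.8, (50, 65), 3, 0.1)
        treat = c.SecretionEstimate(3.4, (100, 120), 4, 0.1)
        assert c.percent_inhibition(base, treat) == pytest.approx(50.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(SecretionError):
            c.percent_inhibition(0.0, 1.0)

    def test_per_animal_then_average(self):
        pairs = [(6.0, 3.0), (8.0, 6.0)]
        mean, sem = c.mean_percent_inhibition(pairs)
        assert mean == pytest.approx((50.0 + 25.0) / 2)
        assert sem > 0


class TestOsmoticChallengeSlope:
    def test_exact_line_recovered(self):
        x = np.linspace(-50, 50, 11)
        d = c.OsmoticChallengeDataset(x, 6.8 + 0.02 * x)
        fit = c.osmotic_challenge_slope(d)
        assert fit.slope_ul_min_mosm == pytest.approx(0.02, rel=1e-12)
        assert fit.intercept_ul_min == pytest.approx(6.8, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_response_gives_zero_slope(self):
        d = c.OsmoticChallengeDataset(np.linspace(-50, 50, 11), np.full(11, 6.8))
        assert c.osmotic_challenge_slope(d).slope_ul_min_mosm == pytest.approx(0.0)

    def test_constant_x_is_singular(self):
        d = c.OsmoticChallengeDataset(np.zeros(5), np.arange(5.0))
        with pytest.raises(SecretionError, match="singular"):
            c.osmotic_challenge_slope(d)

    def test_too_few_animals_rejected(self):
        d = c.OsmoticChallengeDataset(np.array([0.0, 1.0]), np.array([6.8, 6.9]))
        with pytest.raises(SecretionError):
            c.osmotic_challenge_slope(d)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(-50, 50, 11)
        y = 6.8 + 0.023 * x + rng.normal(0, 0.7, 11)
        fit = c.osmotic_challenge_slope(c.OsmoticChallengeDataset(x, y))
        slope, intercept, r2 = ols_normal_equations(x, y)
        assert fit.slope_ul_min_mosm == pytest.approx(slope, rel=1e-10)
        assert fit.intercept_ul_min == pytest.approx(intercept, rel=1e-10)
        assert fit.r_squared == pytest.approx(r2, rel=1e-10)

    def test_recovery_under_calibrated_noise(self):
        # truth 0.023 ul/min/mOsm at noise tuned to the published R^2
        slopes = []
        for seed in range(500):
            d = c.gen_osmotic_challenge(lp=0.023 / 4.6 / 60.0, area=4.6, seed=seed)
            slopes.append(c.osmotic_challenge_slope(d).slope_ul_min_mosm)
        assert np.mean(slopes) == pytest.approx(0.023, abs=0.002)
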