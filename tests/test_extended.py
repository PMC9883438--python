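"""Extended-model pointwise maps, simulation law, MLE and diagnostics."""

import numpy as np
import pytest
from scipy import stats

from cushingsr import (
    AbundanceSeries,
    CycleSeries,
    ExtendedParams,
    ValidationError,
    b_of_T,
    cushing_median,
    fit_extended,
    median_response,
    prediction_band,
    recruitment_rate,
    residual_diagnostics,
    response_cdf,
    response_quantile,
    simulate_response,
)


@pytest.fixture
def table_params(study_truth):
    return study_truth


class TestPointwiseMaps:
    def test_exponent_is_linear_in_T(self, table_params):
        assert b_of_T(table_params, 0.0) == pytest.approx(0.999)
        assert b_of_T(table_params, 1.0) == pytest.approx(0.999 - 0.615)
        flat = ExtendedParams(a=2.0, gamma0=1.4, gamma1=0.0, sigma=1.0)
        for t in (-3.0, 0.0, 7.5):
            assert b_of_T(flat, t) == 1.4

    def test_median_at_unit_stock_is_a(self, table_params):
        for t in (-0.5, 0.0, 0.5):
            assert median_response(table_params, 1.0, t) == pytest.approx(264.299)

    def test_median_reduces_to_static_cushing_when_gamma1_zero(self, rng):
        p = ExtendedParams(a=12.0, gamma0=1.1, gamma1=0.0, sigma=3.0)
        static = p.static()
        for _ in range(20):
            s, t = rng.uniform(1, 5000), rng.uniform(-1, 1)
            assert median_response(p, s, t) == pytest.approx(cushing_median(s, static))

    def test_median_direct_evaluation(self, table_params):
        expected = 264.299 * 500.0 ** (0.999 - 0.615 * 0.2)
        assert median_response(table_params, 500.0, 0.2) == pytest.approx(expected, rel=1e-12)

    def test_recruitment_rate_constant_for_linear_model(self):
        p = ExtendedParams(a=7.0, gamma0=1.0, gamma1=0.0, sigma=1.0)
        for s in (1.0, 10.0, 2500.0):
            assert recruitment_rate(p, s, 0.3) == pytest.approx(7.0)

    def test_recruitment_rate_is_derivative_of_median(self, table_params, rng):
        for _ in range(25):
            s = rng.uniform(2, 3000)
            t = rng.uniform(-0.4, 0.4)
            h = s * 1e-6
            numeric = (
                median_response(table_params, s + h, t)
                - median_response(table_params, s - h, t)
            ) / (2 * h)
            assert recruitment_rate(table_params, s, t) == pytest.approx(numeric, rel=1e-6)

    def test_warming_depresses_recruitment_rate(self, table_params):
        assert recruitment_rate(table_params, 1000.0, 0.3) < recruitment_rate(
            table_params, 1000.0, -0.3
        )


class TestSimulation:
    def test_zero_sigma_returns_median_exactly(self, rng):
        p = ExtendedParams(a=264.299, gamma0=0.999, gamma1=-0.615, sigma=0.0)
        for _ in range(10):
            s, t = rng.uniform(1, 3000), rng.uniform(-0.3, 0.3)
            assert simulate_response(p, s, t, rng) == median_response(p, s, t)

    def test_seeded_draws_are_reproducible(self, table_params):
        d1 = simulate_response(table_params, 500.0, 0.1, 123, size=50)
        d2 = simulate_response(table_params, 500.0, 0.1, 123, size=50)
        assert np.array_equal(d1, d2)

    def test_moments_match_closed_form(self, table_params):
        mu = np.sqrt(median_response(table_params, 800.0, 0.1))
        sig = table_params.sigma
        n = 200_000
        draws = simulate_response(table_params, 800.0, 0.1, 7, size=n)
        exp_mean = mu**2 + sig**2 / 4
        exp_var = mu**2 * sig**2 + sig**4 / 8
        se_mean = np.sqrt(exp_var / n)
        assert abs(draws.mean() - exp_mean) < 3 * se_mean
        m4 = np.mean((draws - draws.mean()) ** 4)
        se_var = np.sqrt(max(m4 - exp_var**2, 0) / n)
        assert abs(draws.var() - exp_var) < 3 * se_var

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            ExtendedParams(a=1.0, gamma0=1.0, gamma1=0.0, sigma=-0.1)


def _make_dataset(params, years, S, T, seed=None):
    if params.sigma == 0 or seed is None:
        r = params.a * S ** (params.gamma0 + params.gamma1 * T)
    else:
        r = simulate_response(params, S, T, seed)
    return AbundanceSeries(years, S, r), CycleSeries(years=years, T=T)


class TestFit:
    def test_noise_free_exact_recovery(self, cycle26):
        years = np.arange(1984, 2021)
        S = np.geomspace(6, 2728, years.size)
        T = cycle26.value(years - 3)
        truth = ExtendedParams(a=264.299, gamma0=0.999, gamma1=-0.615, sigma=0.0)
        ab, cyc = _make_dataset(truth, years, S, T)
        fit = fit_extended(ab, cyc)
        assert fit.params.a == pytest.approx(truth.a, rel=1e-6)
        assert fit.params.gamma0 == pytest.approx(truth.gamma0, abs=1e-7)
        assert fit.params.gamma1 == pytest.approx(truth.gamma1, abs=1e-6)
        assert fit.params.sigma == pytest.approx(0.0, abs=1e-4)

    def test_ci_ordering_and_residual_count(self, study_config):
        from cushingsr import generate_dataset

        ab, cyc, _ = generate_dataset(study_config)
        fit = fit_extended(ab, cyc)
        est = {"a": fit.params.a, "gamma0": fit.params.gamma0, "gamma1": fit.params.gamma1}
        for name, val in est.items():
            lo, hi = fit.ci95[name]
            assert lo < val < hi
            assert 0 <= fit.pvalue[name] <= 1
        assert fit.residuals.size == len(ab)
        assert fit.dof == len(ab) - 3

    def test_loglik_beats_grid_oracle_small_n(self, rng):
        """Optimizer's profiled likelihood >= brute-force 4-D grid (n=6)."""
        years = np.arange(2000, 2006)
        S = np.array([20.0, 45.0, 90.0, 160.0, 300.0, 600.0])
        T = np.array([0.2, 0.1, -0.05, -0.15, -0.2, -0.1])
        truth = ExtendedParams(a=50.0, gamma0=1.0, gamma1=-0.5, sigma=8.0)
        ab, cyc = _make_dataset(truth, years, S, T, seed=5)
        fit = fit_extended(ab, cyc, sigma_estimator="ml")
        sqrt_r = np.sqrt(ab.R)

        def loglik(a, g0, g1, sig):
            mu = np.sqrt(a * S ** (g0 + g1 * T))
            return float(np.sum(stats.norm.logpdf(sqrt_r, mu, sig / 2)))

        best = -np.inf
        for a in np.geomspace(20, 120, 25):
            for g0 in np.linspace(0.7, 1.3, 25):
                for g1 in np.linspace(-1.2, 0.2, 25):
                    for sig in np.linspace(2, 20, 25):
                        best = max(best, loglik(a, g0, g1, sig))
        assert fit.loglik >= best - 1e-9
        assert fit.loglik == pytest.approx(
            loglik(fit.params.a, fit.params.gamma0, fit.params.gamma1, fit.params.sigma)
        )

    def test_degenerate_climate_refused_then_fixable(self):
        years = np.arange(2000, 2010)
        S = np.geomspace(10, 500, years.size)
        T = np.zeros(years.size)
        truth = ExtendedParams(a=30.0, gamma0=1.1, gamma1=0.0, sigma=4.0)
        ab, cyc = _make_dataset(truth, years, S, T, seed=2)
        with pytest.raises(ValidationError, match="fix_gamma1"):
            fit_extended(ab, cyc)
        fit = fit_extended(ab, cyc, fix_gamma1=0.0)
        assert fit.params.gamma1 == 0.0
        assert fit.params.gamma0 == pytest.approx(1.1, abs=0.1)

    def test_mismatched_years_rejected(self, cycle26):
        years = np.arange(2000, 2010)
        S = np.geomspace(10, 500, years.size)
        ab, _ = _make_dataset(
            ExtendedParams(a=30.0, gamma0=1.1, gamma1=0.0, sigma=0.0),
            years, S, np.zeros(years.size),
        )
        cyc = CycleSeries(years=years + 1, T=cycle26.value(years + 1))
        with pytest.raises(ValidationError):
            fit_extended(ab, cyc)


class TestPredictionBand:
    def test_zero_sigma_band_is_degenerate(self):
        p = ExtendedParams(a=100.0, gamma0=1.0, gamma1=-0.5, sigma=0.0)
        band = prediction_band(p, [2000, 2001], [50.0, 100.0], [0.1, -0.1])
        f = band.frame
        assert np.allclose(f["lower"], f["median"])
        assert np.allclose(f["median"], f["upper"])
        assert np.allclose(f["median"], [median_response(p, 50.0, 0.1),
                                         median_response(p, 100.0, -0.1)])

    @pytest.mark.parametrize("mu,s", [(3.0, 2.0), (50.0, 25.0), (500.0, 25.0)])
    @pytest.mark.parametrize("level", [0.025, 0.5, 0.975])
    def test_quantile_inverts_cdf(self, mu, s, level):
        q = response_quantile(level, mu, s)
        assert response_cdf(q, mu, s) == pytest.approx(level, abs=1e-8)

    def test_band_is_positively_skewed_and_widens_with_median(self, table_params):
        S = np.array([10.0, 100.0, 1000.0, 2500.0])
        band = prediction_band(table_params, np.arange(4), S, np.zeros(4))
        f = band.frame
        assert np.all(f["lower"] <= f["median"]) and np.all(f["median"] <= f["upper"])
        up = f["upper"] - f["median"]
        down = f["median"] - f["lower"]
        assert np.all(up > down)  # positive skew at symmetric levels
        widths = (f["upper"] - f["lower"]).to_numpy()
        assert np.all(np.diff(widths) > 0)  # variance grows with the median

    def test_bad_levels_rejected(self, table_params):
        with pytest.raises(ValueError):
            prediction_band(table_params, [2000], [10.0], [0.0], levels=(0.0, 0.975))
        with pytest.raises(ValueError):
            response_quantile(1.2, 10.0, 1.0)


class TestDiagnostics:
    def test_null_calibration(self):
        """i.i.d. normal residuals: each test passes at alpha=0.05 in >=90% of reps."""
        rng = np.random.default_rng(101)
        norm_ok = indep_ok = 0
        reps = 200
        for _ in range(reps):
            rep = residual_diagnostics(rng.standard_normal(37))
            norm_ok += rep.normal_ok
            indep_ok += rep.independent_ok
        assert norm_ok / reps >= 0.90
        assert indep_ok / reps >= 0.90

    def test_detects_serial_dependence(self):
        rng = np.random.default_rng(202)
        hits = 0
        reps = 100
        for _ in range(reps):
            e = rng.standard_normal(37)
            ar = np.empty(37)
            ar[0] = e[0]
            for i in range(1, 37):
                ar[i] = 0.9 * ar[i - 1] + e[i]
            if not residual_diagnostics(ar).independent_ok:
                hits += 1
        assert hits / reps >= 0.90

    def test_detects_skewness(self):
        rng = np.random.default_rng(303)
        hits = 0
        reps = 100
        for _ in range(reps):
            res = np.exp(rng.standard_normal(37))
            if not residual_diagnostics(res).normal_ok:
                hits += 1
        assert hits / reps >= 0.90

    def test_too_few_residuals_rejected(self):
        with pytest.raises(ValidationError):
            residual_diagnostics(np.ones(5))
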