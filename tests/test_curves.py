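import numpy as np
import pytest
from scipy import stats

from bap1timing import (
    FAMILIES,
    InvalidInputError,
    UnfittedCurveError,
    evaluate,
    fit_all_families,
    fit_curve,
    model_summary_table,
    zero_crossing_volume,
)

LN_Y_FAMILIES = ("compound", "power", "S", "growth", "exponential", "logistic")

rng = np.random.default_rng(20240901)
X = rng.uniform(10, 3000, 40)


class TestFitCurve:
    def test_noiseless_linear_recovery(self):
        y = 0.017 * X + 29.03
        fit = fit_curve(X, y, "linear")
        assert fit.fitted
        assert fit.coefficients[0] == pytest.approx(29.03, abs=1e-8)
        assert fit.coefficients[1] == pytest.approx(0.017, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.p_value < 1e-10

    @pytest.mark.parametrize("family", LN_Y_FAMILIES)
    def test_zero_proportion_excludes_log_families(self, family):
        y = 0.017 * X + 29.03
        y[0] = 0.0
        fit = fit_curve(X, y, family)
        assert not fit.fitted
        assert "could not be fitted" in fit.reason
        assert fit.coefficients == ()

    @pytest.mark.parametrize("family", FAMILIES)
    def test_order_invariance(self, family):
        y = np.clip(0.017 * X + 29.03 + rng.normal(0, 10, len(X)), 1, 99)
        a = fit_curve(X, y, family)
        perm = rng.permutation(len(X))
        b = fit_curve(X[perm], y[perm], family)
        assert a.fitted == b.fitted
        np.testing.assert_allclose(a.coefficients, b.coefficients, rtol=1e-8)
        assert a.r_squared == pytest.approx(b.r_squared)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_noiseless_self_consistency(self, family):
        """Fit, then refit on the fitted values: coefficients reproduce."""
        y = np.clip(0.015 * X + 25 + rng.normal(0, 8, len(X)), 1, 99)
        fit = fit_curve(X, y, family)
        assert fit.fitted
        refit = fit_curve(X, evaluate(fit, X), family)
        np.testing.assert_allclose(refit.coefficients, fit.coefficients, rtol=1e-6)
        assert refit.r_squared == pytest.approx(1.0)

    def test_too_few_points(self):
        fit = fit_curve([1, 2, 3], [1, 2, 3], "cubic")
        assert not fit.fitted

    def test_f_statistic_matches_rss_oracle(self):
        """F from R^2 equals the ANOVA F computed from raw residual sums."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.uniform(1, 100, 20)
            y = 5 + 0.3 * x + r.normal(0, 5, 20)
            for family, k in (("linear", 1), ("quadratic", 2), ("cubic", 3)):
                fit = fit_curve(x, y, family)
                pred = evaluate(fit, x)
                rss = np.sum((y - pred) ** 2)
                tss = np.sum((y - y.mean()) ** 2)
                n = len(x)
                f_oracle = ((tss - rss) / k) / (rss / (n - k - 1))
                assert fit.f_statistic == pytest.approx(f_oracle, rel=1e-8)
                assert fit.p_value == pytest.approx(
                    stats.f.sf(f_oracle, k, n - k - 1), rel=1e-8)

    def test_nested_polynomials_r2_monotone(self):
        y = np.clip(0.017 * X + 29 + rng.normal(0, 20, len(X)), 0, 100)
        fits = {f: fit_curve(X, y, f) for f in ("linear", "quadratic", "cubic")}
        assert fits["cubic"].r_squared >= fits["quadratic"].r_squared - 1e-12
        assert fits["quadratic"].r_squared >= fits["linear"].r_squared - 1e-12


class TestEvaluate:
    def test_published_linear_at_348(self, published_fits):
        assert evaluate(published_fits["linear"], 348) == pytest.approx(34.946)

    def test_published_logarithmic_intercept(self, published_fits):
        assert evaluate(published_fits["logarithmic"], 1.0) == pytest.approx(-18.28)

    def test_published_cubic_at_348(self, published_fits):
        assert evaluate(published_fits["cubic"], 348) == pytest.approx(34.5, abs=0.05)

    def test_unfitted_raises(self):
        fit = fit_curve([1, 2, 3, 4, 5, 6], [0, 1, 2, 3, 4, 5], "compound")
        assert not fit.fitted
        with pytest.raises(UnfittedCurveError):
            evaluate(fit, 10)


class TestZeroCrossing:
    def test_published_logarithmic_root(self, published_fits):
        root = zero_crossing_volume(published_fits["logarithmic"], 3000)
        assert root == pytest.approx(np.exp(18.28 / 10.02))
        assert round(root) == 6

    def test_published_linear_clamps_to_zero(self, published_fits):
        # analytic root at a negative volume: no crossing in range
        assert zero_crossing_volume(published_fits["linear"], 3000) == 0.0

    def test_published_quadratic_clamps_to_zero(self, published_fits):
        assert zero_crossing_volume(published_fits["quadratic"], 3000) == 0.0

    def test_published_cubic_large_root_out_of_range(self, published_fits):
        # real root near 6e3 mm^3 sits far outside cohort volumes
        assert zero_crossing_volume(published_fits["cubic"], 3000) == 0.0
        assert zero_crossing_volume(published_fits["cubic"], 10_000) == pytest.approx(
            6040, rel=0.01)

    def test_simple_analytic_root(self):
        x = np.linspace(1, 10, 10)
        fit = fit_curve(x, x - 5.0, "linear")
        assert zero_crossing_volume(fit, 10) == pytest.approx(5.0)

    def test_root_evaluates_to_zero(self, published_fits):
        root = zero_crossing_volume(published_fits["logarithmic"], 3000)
        assert evaluate(published_fits["logarithmic"], root) == pytest.approx(
            0.0, abs=1e-6)

    def test_unfitted_raises(self):
        fit = fit_curve([1, 2, 3, 4, 5, 6], [0, 1, 2, 3, 4, 5], "compound")
        with pytest.raises(UnfittedCurveError):
            zero_crossing_volume(fit, 100)


class TestModelSummaryTable:
    def test_all_families_reported(self):
        y = np.clip(0.017 * X + 29.03 + rng.normal(0, 20, len(X)), 0, 100)
        y[0] = 0.0  # force the log-transform exclusions
        fits = fit_all_families(X, y)
        table = model_summary_table(fits)
        assert list(table["family"]) == list(FAMILIES)
        fitted = set(table.loc[table["fitted"], "family"])
        assert {"linear", "logarithmic", "quadratic", "cubic"} <= fitted
        assert all("could not be fitted" in r
                   for r in table.loc[~table["fitted"], "reason"])

    def test_all_unfitted_input(self):
        y = np.zeros(10)
        x = np.linspace(1, 10, 10)
        fits = [fit_curve(x, y, f) for f in LN_Y_FAMILIES]
        table = model_summary_table(fits)
        assert not table["fitted"].any()
        assert (table["function"] == "").all()

    def test_noiseless_row(self):
        x = np.linspace(1, 100, 30)
        table = model_summary_table([fit_curve(x, 2 * x + 1, "linear")])
        assert table.loc[0, "r_squared"] == pytest.approx(1.0)
        assert table.loc[0, "p_value"] < 1e-10
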