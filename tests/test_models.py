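"""Model zoo: closed-form values, derivatives, fitting and goodness of fit."""

import math
import zlib

import numpy as np
import pytest

from caulipheno.models import (CURD_MODELS, LEAF_MODELS, MODEL_ZOO, DomainError,
                               FitOptions, compare_models, evaluate_model,
                               fit_model, get_model, goodness_of_fit)

from conftest import RICHARDS_TRUTH, series_from

# representative in-domain parameter draws per model for property tests
PARAM_RANGES = {
    "linear": [("a", 0.5, 50), ("b", -10, 100)],
    "power": [("a", 0.1, 20), ("b", 0.3, 3.0)],
    "quadratic": [("a", -2, 2), ("b", -10, 10), ("c", -50, 50)],
    "logistic": [("a", 100, 20000), ("b", 5, 1e4), ("k", 0.05, 0.4)],
    "gompertz": [("a", 100, 20000), ("b", 5, 1e3), ("k", 0.05, 0.4)],
    "richards": [("a", 100, 20000), ("k", 0.05, 0.4), ("tc", 20, 80),
                 ("d", 1.1, 4.0)],
    "sine": [("y0", 100, 500), ("A", 50, 400), ("tc", 60, 120), ("w", 20, 80)],
    "exponential": [("a", 0.5, 50), ("b", 0.01, 0.1)],
}


def _draw_params(name, rng):
    return np.array([rng.uniform(lo, hi) for _, lo, hi in PARAM_RANGES[name]])


class TestEvaluate:
    def test_logistic_half_asymptote_at_origin(self):
        # b = 1 makes the curve pass through a/2 at t = 0
        assert evaluate_model("logistic", {"a": 100, "b": 1, "k": 0.3}, 0.0) == pytest.approx(50.0)

    def test_richards_reduces_to_logistic_at_d2(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(0, 60, 20)
        r = evaluate_model("richards", {"a": 100, "k": 0.2, "tc": 15, "d": 2.0}, t)
        logistic = 100.0 / (1.0 + np.exp(-0.2 * (t - 15.0)))
        np.testing.assert_allclose(r, logistic, rtol=0, atol=1e-9)

    @pytest.mark.parametrize(
        "t, expected",
        [
            (100.0, 300.0),   # quarter period past tc: y0 + A
            (85.0, 150.0),    # zero phase: y0
            (77.5, 150.0 + 150.0 * math.sin(-math.pi / 4)),  # ~43.93
        ],
    )
    def test_sine_hand_values(self, t, expected):
        params = {"y0": 150, "A": 150, "tc": 85, "w": 30}
        assert evaluate_model("sine", params, t) == pytest.approx(expected, abs=1e-9)

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(DomainError):
            evaluate_model("logistic", {"a": np.nan, "b": 1, "k": 0.1}, 1.0)

    def test_richards_shape_below_one_is_domain_error(self):
        with pytest.raises(DomainError):
            evaluate_model("richards", {"a": 1, "k": 0.1, "tc": 0, "d": 0.5}, 1.0)


class TestDerivatives:
    @staticmethod
    def _stencil(f, t, h, order):
        """Fourth-order central finite differences (independent oracle)."""
        if order == 1:
            return (-f(t + 2 * h) + 8 * f(t + h) - 8 * f(t - h) + f(t - 2 * h)) / (12 * h)
        if order == 2:
            return (-f(t + 2 * h) + 16 * f(t + h) - 30 * f(t)
                    + 16 * f(t - h) - f(t - 2 * h)) / (12 * h * h)
        return (-f(t + 3 * h) + 8 * f(t + 2 * h) - 13 * f(t + h)
                + 13 * f(t - h) - 8 * f(t - 2 * h) + f(t - 3 * h)) / (8 * h**3)

    @pytest.mark.parametrize("name", sorted(MODEL_ZOO))
    def test_analytic_derivatives_match_finite_differences(self, name):
        """First three derivatives agree with high-order central differences."""
        spec = MODEL_ZOO[name]
        rng = np.random.default_rng(zlib.crc32(name.encode()))
        for _ in range(10):
            p = _draw_params(name, rng)
            t = rng.uniform(5.0, 90.0, 7)
            f = lambda tt: spec.value(p, tt)
            # step per order balances truncation against roundoff
            for order, func, h in ((1, spec.deriv1, 0.01), (2, spec.deriv2, 0.02),
                                   (3, spec.deriv3, 0.05)):
                fd = self._stencil(f, t, h, order)
                # tolerance relative to the derivative's magnitude on this draw
                atol = 1e-6 * max(1.0, float(np.max(np.abs(fd))))
                np.testing.assert_allclose(func(p, t), fd, rtol=1e-6, atol=atol)


class TestGoodnessOfFit:
    def test_perfect_predictions(self):
        g = goodness_of_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], k=1)
        assert g.r2 == 1.0 and g.rmse == 0.0 and g.mae == 0.0
        assert g.reduced_chi_sq == 0.0

    def test_hand_computed_metrics(self):
        # SSres = 1, SStot = 2 -> R2 = 0.5; RMSE = sqrt(1/(3-1-1)) = 1; MAE = 1/3
        g = goodness_of_fit([1, 2, 3], [1, 2, 4], k=1)
        assert g.r2 == pytest.approx(0.5)
        assert g.rmse == pytest.approx(1.0)
        assert g.mae == pytest.approx(1.0 / 3.0)

    def test_reduced_chi_square_df_convention(self):
        # same residuals, sigma = 1, p = 2 fitted parameters -> 1/(3-2) = 1
        g = goodness_of_fit([1, 2, 3], [1, 2, 4], k=1, n_params=2)
        assert g.reduced_chi_sq == pytest.approx(1.0)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1, 2], [1, 2], k=1)

    def test_zero_variance_with_residuals_flagged(self):
        g = goodness_of_fit([2, 2, 2], [1, 2, 3], k=1)
        assert not g.r2_defined and math.isnan(g.r2)


class TestFitModel:
    def test_linear_fit_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        t = np.arange(1.0, 21.0)
        y = 3.0 * t + 7.0 + rng.normal(0, 0.5, t.size)
        fit = fit_model(series_from(t, y), "linear")
        slope, intercept = np.polyfit(t, y, 1)  # closed-form OLS oracle
        assert fit.params["a"] == pytest.approx(slope, rel=1e-6)
        assert fit.params["b"] == pytest.approx(intercept, rel=1e-6)

    def test_zero_noise_richards_recovery(self, clean_leaf_series):
        fit = fit_model(clean_leaf_series, "richards")
        for name, true in RICHARDS_TRUTH.items():
            assert fit.params[name] == pytest.approx(true, rel=1e-3)
        assert fit.r2 >= 0.999999

    def test_refit_same_seed_is_identical(self, clean_curd_series):
        opts = FitOptions(seed=11)
        f1 = fit_model(clean_curd_series, "sine", opts)
        f2 = fit_model(clean_curd_series, "sine", opts)
        assert f1.params == f2.params

    def test_more_starts_never_worsen_objective(self, clean_leaf_series):
        rng = np.random.default_rng(5)
        noisy = series_from(
            clean_leaf_series.days,
            np.clip(clean_leaf_series.values
                    * (1 + 0.05 * rng.standard_normal(len(clean_leaf_series))), 0, None),
        )
        costs = [fit_model(noisy, "richards", FitOptions(n_starts=n, seed=2)).cost
                 for n in (1, 4, 8)]
        assert costs[0] >= costs[1] >= costs[2]

    def test_series_shorter_than_params_rejected(self):
        with pytest.raises(ValueError):
            fit_model(series_from([1, 2, 3], [1, 2, 3]), "richards")

    @pytest.mark.parametrize("name", sorted(MODEL_ZOO))
    def test_noiseless_self_fit_attains_unit_r2(self, name):
        """Each zoo member refits its own noiseless data to R2 >= 1 - 1e-9."""
        rng = np.random.default_rng(7)
        p = _draw_params(name, rng)
        spec = get_model(name)
        if name == "sine":
            # the sine's domain is a monotone half-period arc with a
            # nonnegative trough (y0 >= A)
            names = [n for n, _, _ in PARAM_RANGES[name]]
            p[names.index("y0")] = p[names.index("A")] + rng.uniform(1.0, 50.0)
            tc, w = p[names.index("tc")], p[names.index("w")]
            t = np.linspace(tc - w / 2, tc + w / 2, 30)
        else:
            t = np.linspace(2.0, 90.0, 30)
        y = np.clip(spec.value(p, t), 0.0, None)
        if np.ptp(y) < 1e-6:
            p[0] = abs(p[0]) + 1.0
            y = np.clip(spec.value(p, t), 0.0, None)
        fit = fit_model(series_from(t, y), name)
        assert fit.r2 >= 1 - 1e-9


class TestCompareModels:
    def test_single_spec_returned_as_rank_one(self, clean_leaf_series):
        ranked = compare_models(clean_leaf_series, ["logistic"])
        assert len(ranked) == 1 and ranked[0].model == "logistic"

    def test_generating_sigmoid_ranks_first(self, clean_leaf_series):
        ranked = compare_models(clean_leaf_series, LEAF_MODELS)
        assert ranked[0].model == "richards"
        assert ranked[0].rmse <= ranked[-1].rmse

    def test_generating_sine_ranks_first(self, clean_curd_series):
        ranked = compare_models(clean_curd_series, CURD_MODELS)
        assert ranked[0].model == "sine"
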