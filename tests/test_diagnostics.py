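"""Diagnostics battery checked against closed-form linear-model results."""

from types import SimpleNamespace

import numpy as np
import pytest
from scipy import stats

from sabrefit import ValidationError, aicc, akaike_weights, bands, profile_ci
from sabrefit.diagnostics import (adjusted_r_squared, classify_dependency,
                                  dependency_from_jacobian, r_squared)
from sabrefit.fitting import FitResult, ParamEstimate
from sabrefit.diagnostics import DependencyReport


class TestRSquared:
    def test_perfect_and_null_fits(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(y, y) == 1.0
        assert r_squared(y, np.full_like(y, y.mean())) == 0.0

    def test_adjusted_formula(self):
        assert adjusted_r_squared(0.9, 10, 2) == pytest.approx(1 - 0.1 * 9 / 7)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            r_squared([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


class TestDependency:
    def test_orthogonal_columns_independent(self):
        J = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        assert np.all(dependency_from_jacobian(J) < 1e-6)

    def test_duplicated_parameter_fully_redundant(self):
        col = np.array([1.0, 2.0, 3.0])
        J = np.column_stack([col, col, np.array([1.0, -1.0, 0.5])])
        deps = dependency_from_jacobian(J)
        assert deps[0] == pytest.approx(1.0, abs=1e-12)
        assert deps[1] == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_parameter_rescaling(self):
        rng = np.random.default_rng(0)
        J = rng.normal(size=(30, 3))
        scaled = J * np.array([1.0, 250.0, 1e-4])
        np.testing.assert_allclose(dependency_from_jacobian(J),
                                   dependency_from_jacobian(scaled), atol=1e-10)

    def test_single_free_parameter_has_zero_dependency(self):
        assert dependency_from_jacobian(np.ones((5, 1)))[0] == 0.0

    @pytest.mark.parametrize("value, label", [
        (0.5, "acceptable"), (0.95, "high"),
        (0.995, "unacceptably high"), (0.99995, "ambiguous")])
    def test_classification_thresholds(self, value, label):
        assert classify_dependency(value) == label


# ---------------------------------------------------------------- adapter

class _LinearProblem:
    """Straight-line least squares exposing the refit protocol the
    diagnostics expect, so profile CIs and bands can be checked against
    textbook closed forms."""

    def __init__(self, x, y):
        self.x, self.y = np.asarray(x, float), np.asarray(y, float)
        ident = SimpleNamespace(to_natural=lambda v: v, log10=False)
        self.spec = SimpleNamespace(specs={"a": ident, "b": ident})
        self.internal_bounds = [(-1e6, 1e6), (-1e6, 1e6)]
        self.design = np.column_stack([np.ones_like(self.x), self.x])

    def model_fraction(self, i, theta, grid):
        return theta[0] + theta[1] * np.asarray(grid, float)

    def fit(self):
        theta, *_ = np.linalg.lstsq(self.design, self.y, rcond=None)
        resid = self.design @ theta - self.y
        return theta, float(resid @ resid)

    def solve_fixed(self, fixed, warm):
        theta = np.array(warm, float)
        if "a" in fixed and "b" in fixed:
            theta[:] = [fixed["a"], fixed["b"]]
        elif "b" in fixed:
            theta[1] = fixed["b"]
            theta[0] = np.mean(self.y - theta[1] * self.x)
        elif "a" in fixed:
            theta[0] = fixed["a"]
            theta[1] = float((self.x @ (self.y - theta[0])) / (self.x @ self.x))
        resid = self.design @ theta - self.y
        return theta, float(resid @ resid)


def linear_fit_result(x, y):
    problem = _LinearProblem(x, y)
    theta, ss = problem.fit()
    deps = dependency_from_jacobian(problem.design)
    values = dict(zip(("a", "b"), deps))
    report = DependencyReport(values, {k: classify_dependency(v)
                                       for k, v in values.items()})
    return FitResult(
        params={k: ParamEstimate(v) for k, v in zip(("a", "b"), theta)},
        fixed={}, ss=ss, n_obs=len(x), n_free=2,
        r2_per_dataset={}, r2_global=1.0, r2_adjusted=1.0, aicc=0.0,
        ambiguous=report.ambiguous, dependency_report=report, strategy=None,
        convergence={}, free_keys=["a", "b"],
        _problem=problem, _x=np.asarray(theta), _jac=problem.design)


@pytest.fixture(scope="module")
def linear_fixture():
    rng = np.random.default_rng(11)
    x = np.linspace(0.0, 1.0, 25)
    y = 0.3 + 1.7 * x + rng.normal(0, 0.05, x.size)
    return x, y, linear_fit_result(x, y)


class TestProfileCI:
    def test_matches_closed_form_t_interval(self, linear_fixture):
        x, y, fit = linear_fixture
        lo, hi = profile_ci(fit, "b", level=0.95)
        s2 = fit.ss / (fit.n_obs - 2)
        sxx = float(np.sum((x - x.mean()) ** 2))
        b_hat = fit.params["b"].value
        half = stats.t.ppf(0.975, fit.n_obs - 2) * np.sqrt(s2 / sxx)
        assert lo == pytest.approx(b_hat - half, rel=1e-2)
        assert hi == pytest.approx(b_hat + half, rel=1e-2)

    def test_intervals_are_nested(self, linear_fixture):
        _, _, fit = linear_fixture
        lo95, hi95 = profile_ci(fit, "b", level=0.95)
        lo90, hi90 = profile_ci(fit, "b", level=0.90)
        assert lo95 < lo90 < hi90 < hi95

    def test_level_zero_collapses_to_estimate(self, linear_fixture):
        _, _, fit = linear_fixture
        lo, hi = profile_ci(fit, "b", level=0.0)
        assert lo == hi == fit.params["b"].value

    def test_interval_contains_best_fit(self, linear_fixture):
        _, _, fit = linear_fixture
        lo, hi = profile_ci(fit, "a", level=0.95)
        assert lo < fit.params["a"].value < hi


class TestBands:
    def test_halfwidth_at_mean_x_is_t_s_over_sqrt_n(self, linear_fixture):
        x, y, fit = linear_fixture
        bs = bands(fit, 0, np.array([x.mean()]))
        s = np.sqrt(fit.ss / (fit.n_obs - 2))
        expected = stats.t.ppf(0.975, fit.n_obs - 2) * s / np.sqrt(fit.n_obs)
        assert (bs.conf_hi[0] - bs.best[0]) == pytest.approx(expected, rel=1e-6)

    def test_prediction_band_encloses_confidence_band(self, linear_fixture):
        x, y, fit = linear_fixture
        bs = bands(fit, 0, np.linspace(0, 1, 15))
        assert np.all(bs.pred_lo <= bs.conf_lo)
        assert np.all(bs.pred_hi >= bs.conf_hi)
        assert np.all((bs.conf_lo <= bs.best) & (bs.best <= bs.conf_hi))

    def test_zero_residual_fit_has_collapsing_bands(self):
        x = np.linspace(0, 1, 12)
        fit = linear_fit_result(x, 0.2 + 0.8 * x)  # exact line
        bs = bands(fit, 0, x)
        assert np.all(bs.conf_hi - bs.conf_lo < 1e-6)
        assert np.all(bs.pred_hi - bs.pred_lo < 1e-6)


class TestAICc:
    def test_delta_two_gives_textbook_weights(self):
        w = akaike_weights([0.0, 2.0])
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1.0)), rel=1e-6)
        assert w[1] == pytest.approx(np.exp(-1.0) / (1 + np.exp(-1.0)), rel=1e-6)

    def test_equal_aicc_splits_evenly_and_sums_to_one(self):
        np.testing.assert_allclose(akaike_weights([5.0, 5.0]), [0.5, 0.5])
        rng = np.random.default_rng(3)
        w = akaike_weights(rng.normal(0, 10, 7))
        assert w.sum() == pytest.approx(1.0)

    def test_formula_value(self):
        # n ln(SS/n) + 2k + 2k(k+1)/(n-k-1), k = params + 1
        n, ss, k_params = 20, 0.5, 3
        k = k_params + 1
        expected = n * np.log(ss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert aicc(ss, n, k_params) == pytest.approx(expected)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValidationError):
            aicc(1.0, 5, 4)
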