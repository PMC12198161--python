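"""Fit-quality diagnostics for (global) nonlinear least squares.

Implements the battery used throughout the pipeline:

* R-squared, its adjusted form, and a pooled "global" R-squared for
  multi-dataset fits;
* parameter dependency — a 0-1 measure of how intertwined each free
  parameter is with all the others, with the conventional thresholds
  (> 0.9 high, > 0.99 unacceptably high, > 0.9999 ambiguous);
* asymmetrical (profile-likelihood) confidence intervals, where either
  side may be reported open when the sum of squares never crosses the
  F-based threshold inside the parameter bounds;
* first-order 95% confidence and prediction bands around a fitted curve;
* AICc and Akaike weights ("relative probability of correctness").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DiagnosticsUnavailableError, ValidationError

__all__ = [
    "DependencyReport",
    "BandSet",
    "r_squared",
    "adjusted_r_squared",
    "dependency_from_jacobian",
    "classify_dependency",
    "dependency_report",
    "profile_ci",
    "bands",
    "aicc",
    "akaike_weights",
]

#: Dependency above this value flags the whole fit as ambiguous.
AMBIGUITY_THRESHOLD = 0.9999


# ---------------------------------------------------------------- R-squared

def r_squared(observed, fitted) -> float:
    """Coefficient of determination, SS_tot taken about the mean."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.size < 2:
        raise ValidationError("R^2 requires at least 2 observations")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise ValidationError("R^2 undefined: observations have zero variance")
    ss_res = float(np.sum((observed - fitted) ** 2))
    return 1.0 - ss_res / ss_tot


def adjusted_r_squared(r2: float, n_obs: int, n_params: int) -> float:
    """1 - (1 - R^2)(N - 1)/(N - p - 1)."""
    if n_obs <= n_params + 1:
        raise ValidationError("adjusted R^2 requires n_obs > n_params + 1")
    return 1.0 - (1.0 - r2) * (n_obs - 1) / (n_obs - n_params - 1)


# ---------------------------------------------------------------- dependency

def dependency_from_jacobian(jac: np.ndarray) -> np.ndarray:
    """Per-parameter dependency from the residual Jacobian at the solution.

    dependency_i = 1 - 1/VIF_i, where VIF_i is the i-th diagonal of the
    inverse of the correlation matrix of the parameter estimates implied by
    the Gauss-Newton covariance (J^T J)^-1. Algebraically this equals the
    (uncentred) R^2 of regressing Jacobian column i on all other columns,
    which is the form computed here: it remains finite and -> 1 under exact
    collinearity, so rank-deficient fits come out redundant rather than
    raising. Values are clipped to [0, 1]; a single free parameter has
    dependency 0 by convention.
    """
    jac = np.asarray(jac, dtype=float)
    if jac.ndim != 2:
        raise DiagnosticsUnavailableError("Jacobian must be a 2-D array")
    n_params = jac.shape[1]
    if n_params < 2:
        return np.zeros(n_params)
    deps = np.empty(n_params)
    for i in range(n_params):
        col = jac[:, i]
        total = float(col @ col)
        if total == 0 or not np.isfinite(total):
            deps[i] = 1.0  # parameter without influence: fully redundant
            continue
        others = np.delete(jac, i, axis=1)
        coef, *_ = np.linalg.lstsq(others, col, rcond=None)
        resid = col - others @ coef
        deps[i] = 1.0 - float(resid @ resid) / total
    return np.clip(deps, 0.0, 1.0)


def classify_dependency(value: float) -> str:
    if value > AMBIGUITY_THRESHOLD:
        return "ambiguous"
    if value > 0.99:
        return "unacceptably high"
    if value > 0.9:
        return "high"
    return "acceptable"


@dataclass(frozen=True)
class DependencyReport:
    values: dict  # parameter key -> dependency in [0, 1]
    classifications: dict  # parameter key -> label

    @property
    def ambiguous(self) -> bool:
        return any(v > AMBIGUITY_THRESHOLD for v in self.values.values())


def dependency_report(fit) -> DependencyReport:
    """Dependency report for a converged :class:`~sabrefit.fitting.FitResult`."""
    if getattr(fit, "_jac", None) is None:
        raise DiagnosticsUnavailableError("fit carries no Jacobian")
    keys = fit.free_keys
    deps = dependency_from_jacobian(fit._jac)
    values = dict(zip(keys, deps))
    return DependencyReport(values, {k: classify_dependency(v) for k, v in values.items()})


# ------------------------------------------------------- profile likelihood

def _ss_threshold(ss_min: float, n_obs: int, n_free: int, level: float) -> float:
    dof = n_obs - n_free
    if dof <= 0:
        raise DiagnosticsUnavailableError("no residual degrees of freedom")
    fval = stats.f.ppf(level, 1, dof)
    return ss_min * (1.0 + fval / dof)


def profile_ci(fit, key: str, level: float = 0.95):
    """Profile-likelihood interval for one free parameter (natural scale).

    The interval collects parameter values whose profiled sum of squares
    (all other free parameters re-optimised) stays below
    SS_min * (1 + F(1, N-p; level)/(N-p)). A side that never crosses the
    threshold before hitting the parameter's bound is reported as ``None``
    (open, rendered "?"). The best-fit value always lies inside.
    """
    problem = getattr(fit, "_problem", None)
    if problem is None:
        raise DiagnosticsUnavailableError("fit carries no refit problem")
    keys = fit.free_keys
    if key not in keys:
        raise ValidationError(f"{key!r} is not a free parameter of this fit")
    idx = keys.index(key)
    spec = problem.spec.specs[key]
    x_best = fit._x.copy()
    theta = x_best[idx]

    if level <= 0:
        val = spec.to_natural(theta)
        return (val, val)
    crit = _ss_threshold(fit.ss, fit.n_obs, fit.n_free, level)
    if fit.ss == 0 or crit <= fit.ss:
        val = spec.to_natural(theta)
        return (val, val)

    lo_b, hi_b = problem.internal_bounds[idx]

    def profiled_ss(v: float) -> float:
        return problem.solve_fixed({key: v}, warm=x_best)[1]

    def one_side(direction: int):
        bound = hi_b if direction > 0 else lo_b
        step = max(0.05 * abs(theta), 0.01)
        inside = theta
        for _ in range(60):
            probe = theta + direction * step
            hit_bound = (probe >= bound) if direction > 0 else (probe <= bound)
            if hit_bound:
                probe = bound
            ss = profiled_ss(probe)
            if ss > crit:
                # bracket found between `inside` and `probe`
                from scipy.optimize import brentq
                try:
                    root = brentq(lambda v: profiled_ss(v) - crit, *sorted((inside, probe)),
                                  xtol=1e-8 * max(1.0, abs(theta)), rtol=1e-6)
                except ValueError:
                    return None
                return spec.to_natural(root)
            if hit_bound:
                return None  # open side: threshold never crossed within bounds
            inside = probe
            step *= 2.0
        return None

    lo = one_side(-1)
    hi = one_side(+1)
    if spec.log10:  # monotone transform keeps ordering
        return (lo, hi)
    return (lo, hi)


# ----------------------------------------------------------------- bands

@dataclass(frozen=True)
class BandSet:
    """Best-fit curve with pointwise 95% confidence and prediction bands."""

    grid: np.ndarray  # molar concentrations
    best: np.ndarray  # fractional effect
    conf_lo: np.ndarray
    conf_hi: np.ndarray
    pred_lo: np.ndarray
    pred_hi: np.ndarray


def bands(fit, dataset_index: int, grid, level: float = 0.95) -> BandSet:
    """First-order (delta-method) confidence and prediction bands.

    The confidence band propagates the Gauss-Newton parameter covariance
    through the model gradient at each grid point; the prediction band adds
    the residual variance under the same t quantile. The prediction band
    encloses the confidence band pointwise by construction.
    """
    problem = getattr(fit, "_problem", None)
    if problem is None or fit._jac is None:
        raise DiagnosticsUnavailableError("fit carries no Jacobian/problem")
    grid = np.asarray(grid, dtype=float)
    dof = fit.n_obs - fit.n_free
    if dof <= 0:
        raise DiagnosticsUnavailableError("no residual degrees of freedom")
    s2 = fit.ss / dof
    cov = s2 * np.linalg.pinv(fit._jac.T @ fit._jac)
    tq = stats.t.ppf(0.5 + level / 2.0, dof)

    x = fit._x
    best = problem.model_fraction(dataset_index, x, grid)
    grads = np.empty((grid.size, len(x)))
    for j in range(len(x)):
        h = 1e-6 * max(1.0, abs(x[j]))
        xp = x.copy(); xp[j] += h
        xm = x.copy(); xm[j] -= h
        grads[:, j] = (problem.model_fraction(dataset_index, xp, grid)
                       - problem.model_fraction(dataset_index, xm, grid)) / (2 * h)
    var_conf = np.maximum(np.einsum("ij,jk,ik->i", grads, cov, grads), 0.0)
    half_conf = tq * np.sqrt(var_conf)
    half_pred = tq * np.sqrt(var_conf + s2)
    return BandSet(grid, best, best - half_conf, best + half_conf,
                   best - half_pred, best + half_pred)


# ------------------------------------------------------------------- AICc

def aicc(ss: float, n_obs: int, k_params: int) -> float:
    """Small-sample-corrected Akaike information criterion for an
    unweighted least-squares fit.

    k counts the fitted parameters plus one for the residual variance:
    AICc = n ln(SS/n) + 2k + 2k(k+1)/(n - k - 1).
    """
    if ss <= 0:
        raise ValidationError("AICc requires a positive residual sum of squares")
    k = k_params + 1
    if n_obs - k - 1 <= 0:
        raise ValidationError("AICc correction undefined: too few observations")
    return n_obs * np.log(ss / n_obs) + 2 * k + 2 * k * (k + 1) / (n_obs - k - 1)


def akaike_weights(aiccs) -> np.ndarray:
    """exp(-delta/2) normalised over the candidate models; sums to 1."""
    a = np.asarray(aiccs, dtype=float)
    if a.size == 0:
        raise ValidationError("at least one AICc value required")
    rel = np.exp(-(a - a.min()) / 2.0)
    return rel / rel.sum()
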