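"""Rescaling of raw effects to percent of the system maximum.

The system maximum is defined as the largest Hill-fit Emax among the naive
("N") datasets: every curve in the study is then expressed as
100 * effect / system_emax, so the strongest naive curve tops out at 100%.
Hill fits leave Emax, logEC50 and nH all free; fits are unweighted on the
mean effects (SEMs are metadata and are rescaled by the same factor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .data import ECDataset
from .errors import ConfigurationError, FitFailureError, ValidationError
from .models import HillParams, hill_effect

__all__ = ["HillFit", "NormalizationResult", "fit_hill", "normalize_study"]

_LS_OPTS = dict(method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000)


@dataclass(frozen=True)
class HillFit:
    """A converged Hill fit: parameters plus goodness-of-fit."""

    params: HillParams
    rss: float
    n_obs: int


@dataclass
class NormalizationResult:
    system_emax: float  # largest naive-curve Hill Emax, raw units
    hill_fits: dict  # dataset name -> HillFit (naive datasets)
    datasets: list  # all datasets rescaled by 100 / system_emax


def _hill_residual(theta, c, y):
    emax, logec50, nh = theta
    return hill_effect(c, HillParams(emax, logec50, nh)) - y


def fit_hill(ds: ECDataset, init: HillParams | None = None,
             weighted: bool = False) -> HillFit:
    """Fit the Hill equation to one dataset by least squares.

    Three deterministic starts are tried (EC50 at the geometric mean of the
    concentration grid and one decade either side); the lowest residual sum
    of squares wins. ``weighted`` divides residuals by the stored SEMs.
    """
    c = ds.concentrations
    y = ds.effects
    mask = c > 0
    if mask.sum() < 4:
        raise ValidationError("Hill fit needs >= 4 positive-concentration points")
    if np.all(y == 0):
        raise FitFailureError(f"{ds.name}: all effects are zero; Hill fit undefined")

    logc = np.log10(c[mask])
    lo_ec, hi_ec = logc.min() - 2.0, logc.max() + 2.0
    lower = np.array([1e-6, lo_ec, 0.2])
    upper = np.array([200.0, hi_ec, 5.0])

    if init is not None:
        starts = [np.clip([init.Emax, init.logEC50, init.nH], lower, upper)]
    else:
        emax0 = np.clip(1.05 * y.max(), 1e-3, 200.0)
        mid = logc.mean()
        starts = [np.clip([emax0, m, 1.0], lower, upper)
                  for m in (mid, mid - 1.0, mid + 1.0)]

    if weighted and ds.sems is not None:
        w = np.where(ds.sems > 0, ds.sems, np.nanmean(ds.sems[ds.sems > 0]))
        resid = lambda th: _hill_residual(th, c, y) / w
    else:
        resid = lambda th: _hill_residual(th, c, y)

    best, tried = None, []
    for x0 in starts:
        sol = least_squares(resid, x0, bounds=(lower, upper), **_LS_OPTS)
        tried.append({"x0": list(x0), "status": sol.status, "cost": sol.cost})
        if sol.status > 0 and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitFailureError(f"{ds.name}: Hill fit did not converge", details=tried)

    rss = float(np.sum(_hill_residual(best.x, c, y) ** 2))
    return HillFit(HillParams(*best.x), rss=rss, n_obs=len(y))


def normalize_study(datasets: list[ECDataset]) -> NormalizationResult:
    """Rescale a study so the largest naive Hill Emax maps to 100%."""
    naive = [ds for ds in datasets if ds.pretreatment == "N"]
    if not naive:
        raise ConfigurationError("normalization requires at least one naive (N) dataset")
    fits = {ds.name: fit_hill(ds) for ds in naive}
    system_emax = max(f.params.Emax for f in fits.values())
    factor = 100.0 / system_emax
    return NormalizationResult(
        system_emax=system_emax,
        hill_fits=fits,
        datasets=[ds.rescaled(factor) for ds in datasets],
    )
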