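"""Deterministic E/c curve simulation over an (epsilon, gamma) grid.

Generates noise-free SABRE curves for every combination of receptor
efficacies and gain factors — the defaults pair a weak partial agonist
(epsilon = 0.17) and a full agonist (epsilon = 1) with signal attenuation
(gamma = 0.3), neutral handling (gamma = 1) and strong amplification
(gamma = 136.8) — and refits each with the Hill equation. For unit slope
the refit is exact: the SABRE curve is itself a hyperbola with asymptote
``sabre_max_fraction`` and EC50 given by the closed form. The grid
demonstrates how amplification lets a weak partial agonist approach the
full-agonist maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitFailureError, ValidationError
from .models import HillParams, SabreParams, hill_langmuir_fraction, sabre_fraction

__all__ = ["SimulationGrid", "SimulatedCurve", "simulate_grid", "hill_refit"]


def _default_conc_grid() -> np.ndarray:
    # wide enough to resolve the left shift of a gamma ~ 137 curve
    return np.logspace(-10, -3, 20)


@dataclass(frozen=True)
class SimulationGrid:
    epsilons: tuple = (0.17, 1.0)
    gammas: tuple = (0.3, 1.0, 136.8)
    n: float = 1.0
    logKd: float = -5.93
    concentrations: np.ndarray = field(default_factory=_default_conc_grid)

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if c.ndim != 1 or len(c) < 4 or np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValidationError(
                "concentration grid must be >= 4 increasing positive values")
        object.__setattr__(self, "concentrations", c)
        for eps in self.epsilons:
            for gam in self.gammas:
                SabreParams(epsilon=eps, gamma=gam, n=self.n, logKd=self.logKd)


@dataclass(frozen=True)
class SimulatedCurve:
    params: SabreParams
    concentrations: np.ndarray
    fractions: np.ndarray


def simulate_grid(grid: SimulationGrid) -> list:
    """One noise-free curve per (epsilon, gamma) combination, q = 1."""
    curves = []
    for eps in grid.epsilons:
        for gam in grid.gammas:
            p = SabreParams(epsilon=eps, gamma=gam, n=grid.n,
                            logKd=grid.logKd, q=1.0)
            curves.append(SimulatedCurve(
                params=p,
                concentrations=grid.concentrations,
                fractions=np.atleast_1d(sabre_fraction(grid.concentrations, p)),
            ))
    return curves


def hill_refit(curve: SimulatedCurve) -> HillParams:
    """Fit the Hill equation to a simulated curve (fractional Emax).

    Warns when the curve does not span at least 90% of its own asymptote
    over the simulated grid (the top of the curve is then poorly defined).
    """
    c, f = curve.concentrations, curve.fractions
    fmax = f.max()
    if fmax <= 0:
        raise FitFailureError("simulated curve is identically zero")
    from .models import sabre_max_fraction
    if fmax < 0.9 * sabre_max_fraction(curve.params):
        warnings.warn("simulated curve spans < 90% of its asymptote; "
                      "Hill refit may be poorly constrained", stacklevel=2)

    logc = np.log10(c)

    def resid(theta):
        emax, logec50, nh = theta
        return emax * hill_langmuir_fraction(c, logec50, nh) - f

    # initial EC50 at the interpolated half-maximum of the simulated curve
    half = 0.5 * fmax
    ec0 = float(np.interp(half, f, logc))
    lower = [1e-9, logc.min() - 3.0, 0.2]
    upper = [2.0, logc.max() + 3.0, 5.0]
    sol = least_squares(resid, np.clip([1.02 * fmax, ec0, 1.0], lower, upper),
                        bounds=(lower, upper), method="trf",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=10000)
    if sol.status <= 0:
        raise FitFailureError("Hill refit of simulated curve did not converge")
    return HillParams(Emax=float(sol.x[0]), logEC50=float(sol.x[1]),
                      nH=float(sol.x[2]))
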