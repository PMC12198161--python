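"""Furchgott's irreversible-antagonism method.

The classical benchmark against which the global SABRE fits are compared:
after partial irreversible receptor inactivation, concentrations on the
naive curve (A) and the treated curve (A') that produce the *same* effect
are related by the double-reciprocal identity

    1/A = (1/q) * (1/A') + (1 - q) / (q * Kd)

so an ordinary least-squares line of 1/A on 1/A' yields the operable
receptor fraction q = 1/slope and Kd = (slope - 1)/intercept.

Equieffective pairs are read off *fitted* Hill curves (raw concentration
grids rarely align across curves); by default 12 effect levels spanning
10-90% of the lower curve's maximum are used, avoiding the unstable
asymptote region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import EstimationError, ValidationError
from .models import HillParams

__all__ = ["EquieffectivePairs", "FurchgottResult", "invert_hill",
           "equieffective_pairs", "furchgott_regression"]


def invert_hill(p: HillParams, effect) -> np.ndarray:
    """Concentration at which a Hill curve reaches ``effect`` (same units
    as the curve's Emax); defined for 0 < effect < Emax."""
    e = np.asarray(effect, dtype=float)
    if np.any(e <= 0) or np.any(e >= p.Emax):
        raise ValidationError("effect must lie strictly within (0, Emax)")
    return p.EC50 * (e / (p.Emax - e)) ** (1.0 / p.nH)


@dataclass(frozen=True)
class EquieffectivePairs:
    levels: np.ndarray  # effect levels (units of the fitted curves)
    A: np.ndarray  # molar concentrations on the naive curve
    A_prime: np.ndarray  # molar concentrations on the treated curve

    def __post_init__(self):
        for name in ("levels", "A", "A_prime"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if not (len(self.levels) == len(self.A) == len(self.A_prime)):
            raise ValidationError("levels, A and A_prime must align")
        if np.any(self.A <= 0) or np.any(self.A_prime <= 0):
            raise ValidationError("concentrations must be > 0")


@dataclass(frozen=True)
class FurchgottResult:
    q: float
    Kd: float  # molar
    slope: float
    intercept: float
    r_squared: float
    n_pairs: int

    @property
    def logKd(self) -> float:
        return float(np.log10(self.Kd))


def equieffective_pairs(naive_fit: HillParams, treated_fit: HillParams,
                        n_levels: int = 12) -> EquieffectivePairs:
    """Equieffective concentration pairs from two fitted Hill curves.

    ``n_levels`` effect values are spaced evenly across 10-90% of the lower
    curve's maximum (which is always inside both curves' ranges), then
    inverted through each Hill curve.
    """
    if n_levels < 1:
        raise ValidationError("n_levels must be >= 1")
    low_max = min(naive_fit.Emax, treated_fit.Emax)
    if low_max <= 0:
        raise ValidationError("curves have no overlapping effect range")
    levels = np.linspace(0.10 * low_max, 0.90 * low_max, n_levels)
    return EquieffectivePairs(
        levels=levels,
        A=invert_hill(naive_fit, levels),
        A_prime=invert_hill(treated_fit, levels),
    )


def furchgott_regression(pairs: EquieffectivePairs) -> FurchgottResult:
    """Estimate (q, Kd) by the double-reciprocal regression.

    Fails with :class:`EstimationError` when the fitted line implies no
    detectable receptor loss (slope <= 1) or a non-positive Kd
    (intercept <= 0).
    """
    if len(pairs.A) < 3:
        raise ValidationError("Furchgott regression needs >= 3 equieffective pairs")
    reg = stats.linregress(1.0 / pairs.A_prime, 1.0 / pairs.A)
    slope, intercept = float(reg.slope), float(reg.intercept)
    if slope <= 1.0:
        raise EstimationError(
            f"slope {slope:.4g} <= 1: no receptor loss detectable")
    if intercept <= 0.0:
        raise EstimationError(
            f"intercept {intercept:.4g} <= 0: Kd estimate would be non-positive")
    return FurchgottResult(
        q=1.0 / slope,
        Kd=(slope - 1.0) / intercept,
        slope=slope,
        intercept=intercept,
        r_squared=float(reg.rvalue) ** 2,
        n_pairs=len(pairs.A),
    )
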