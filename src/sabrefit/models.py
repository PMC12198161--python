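"""Receptor-function model equations.

All functions here are pure and operate on *fractional* effect (0-1 scale,
the effect divided by the maximal effect achievable in the system). The
models implemented:

* the Hill-Langmuir equation (fractional form),
* the SABRE model (Signal Amplification, Binding affinity and
  Receptor-activation Efficacy), which separates receptor activation
  (``epsilon``) from post-receptor signal gain (``gamma``) and supports a
  reduced operable-receptor fraction ``q`` after irreversible inactivation,
* the operational model of agonism (fractional form, parameter ``tau``),
* the empirical Hill equation on the percent scale.

Concentrations are molar; dissociation constants are parametrised as
``logKd`` = log10(Kd / M) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "SabreParams",
    "OperationalParams",
    "HillParams",
    "hill_langmuir_fraction",
    "sabre_fraction",
    "sabre_max_fraction",
    "operational_fraction",
    "hill_effect",
    "closed_form_ec50",
]

# exp() overflows above ~709; treat anything past this as the asymptote
_LOG_HUGE = 600.0


def _check_conc(c):
    c = np.asarray(c, dtype=float)
    if np.any(c < 0) or np.any(~np.isfinite(c)):
        raise ValidationError("concentrations must be finite and >= 0")
    return c


@dataclass(frozen=True)
class SabreParams:
    """Parameter vector of the SABRE model.

    epsilon : receptor-activation efficacy, in [0, 1]
    gamma   : post-receptor gain factor, > 0 (amplification if > 1)
    n       : Hill-type slope factor, > 0
    logKd   : log10 of the agonist-receptor dissociation constant (log10 M)
    q       : fraction of operable receptors after irreversible
              inactivation, in (0, 1]; 1 for naive tissue
    """

    epsilon: float = 1.0
    gamma: float = 1.0
    n: float = 1.0
    logKd: float = -6.0
    q: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValidationError(f"epsilon must be in [0, 1], got {self.epsilon}")
        if not (self.gamma > 0):
            raise ValidationError(f"gamma must be > 0, got {self.gamma}")
        if not (self.n > 0):
            raise ValidationError(f"n must be > 0, got {self.n}")
        if not (0.0 < self.q <= 1.0):
            raise ValidationError(f"q must be in (0, 1], got {self.q}")
        if not np.isfinite(self.logKd):
            raise ValidationError(f"logKd must be finite, got {self.logKd}")

    @property
    def Kd(self) -> float:
        return 10.0 ** self.logKd


@dataclass(frozen=True)
class OperationalParams:
    """Parameter vector of the operational model of agonism.

    tau   : operational efficacy (lumps receptor and post-receptor signal
            handling into one parameter), > 0
    n     : operational slope factor, > 0
    logKd : log10 of the agonist-receptor dissociation constant (log10 M).
            Classical texts write E_m, K_A and n_op; they map onto the
            system E_max (implicit in the fractional form), Kd and n.
    """

    tau: float = 1.0
    n: float = 1.0
    logKd: float = -6.0

    def __post_init__(self):
        if not (self.tau > 0):
            raise ValidationError(f"tau must be > 0, got {self.tau}")
        if not (self.n > 0):
            raise ValidationError(f"n must be > 0, got {self.n}")
        if not np.isfinite(self.logKd):
            raise ValidationError(f"logKd must be finite, got {self.logKd}")

    @property
    def Kd(self) -> float:
        return 10.0 ** self.logKd


@dataclass(frozen=True)
class HillParams:
    """Empirical Hill-equation parameters on the percent-effect scale.

    Emax    : maximal effect of this curve (same units as the data it was
              fitted to, typically % of system maximum)
    logEC50 : log10 of the half-maximal concentration (log10 M)
    nH      : Hill coefficient, > 0
    """

    Emax: float
    logEC50: float
    nH: float = 1.0

    def __post_init__(self):
        if not (self.Emax > 0):
            raise ValidationError(f"Emax must be > 0, got {self.Emax}")
        if not (self.nH > 0):
            raise ValidationError(f"nH must be > 0, got {self.nH}")
        if not np.isfinite(self.logEC50):
            raise ValidationError(f"logEC50 must be finite, got {self.logEC50}")

    @property
    def EC50(self) -> float:
        return 10.0 ** self.logEC50


def _saturation_ratio(c, logK, n):
    """(c/K)^n evaluated safely in log space; 0 where c == 0, inf-safe."""
    c = _check_conc(c)
    with np.errstate(divide="ignore"):
        logt = n * (np.log10(np.where(c > 0, c, 1.0)) - logK) * np.log(10.0)
    t = np.where(c > 0, np.exp(np.clip(logt, -_LOG_HUGE, _LOG_HUGE)), 0.0)
    # flag points past the overflow clip so callers can substitute the asymptote
    saturated = np.where(c > 0, logt >= _LOG_HUGE, False)
    return t, saturated


def hill_langmuir_fraction(c, logKd: float, n: float = 1.0):
    """Fractional receptor occupancy c^n / (c^n + Kd^n)."""
    if not (n > 0):
        raise ValidationError(f"n must be > 0, got {n}")
    t, sat = _saturation_ratio(c, logKd, n)
    frac = np.where(sat, 1.0, t / (t + 1.0))
    return frac if frac.ndim else float(frac)


def sabre_fraction(c, p: SabreParams):
    """Fractional effect under the SABRE model.

    f = q*eps*gamma*c^n / ((q*eps*gamma - q*eps + 1)*c^n + Kd^n)

    With q = 1 this is the naive-tissue form; q < 1 models partial
    irreversible receptor inactivation. Reduces to the Hill-Langmuir
    equation when epsilon = gamma = q = 1.
    """
    if not isinstance(p, SabreParams):
        p = SabreParams(*p) if isinstance(p, (tuple, list)) else p
    a = p.q * p.epsilon * p.gamma
    b = p.q * p.epsilon * p.gamma - p.q * p.epsilon + 1.0
    t, sat = _saturation_ratio(c, p.logKd, p.n)
    with np.errstate(invalid="ignore"):
        frac = np.where(sat, a / b if a > 0 else 0.0, a * t / (b * t + 1.0))
    return frac if frac.ndim else float(frac)


def sabre_max_fraction(p: SabreParams) -> float:
    """Asymptotic fractional effect of a SABRE curve as c -> infinity.

    q*eps*gamma / (q*eps*gamma - q*eps + 1); equals 1 iff q*eps = 1.
    """
    a = p.q * p.epsilon * p.gamma
    if a == 0:
        return 0.0
    return a / (a - p.q * p.epsilon + 1.0)


def operational_fraction(c, p: OperationalParams):
    """Fractional effect under the operational model of agonism.

    f = (c*tau)^n / ((c*tau)^n + (c + Kd)^n)

    Asymptote tau^n / (tau^n + 1) as c -> infinity.
    """
    c = _check_conc(c)
    Kd = p.Kd
    # r = (c*tau / (c + Kd))^n computed in log space; f = r / (1 + r)
    with np.errstate(divide="ignore"):
        logr = p.n * (np.log(np.where(c > 0, c * p.tau, 1.0)) - np.log(c + Kd))
    r = np.where(c > 0, np.exp(np.clip(logr, -_LOG_HUGE, _LOG_HUGE)), 0.0)
    frac = r / (r + 1.0)
    return frac if frac.ndim else float(frac)


def hill_effect(c, p: HillParams):
    """Hill equation on the effect scale: Emax * c^nH / (c^nH + EC50^nH)."""
    occ = hill_langmuir_fraction(c, p.logEC50, p.nH)
    out = p.Emax * np.asarray(occ)
    return out if out.ndim else float(out)


def closed_form_ec50(model: str, params) -> float:
    """Analytic half-maximal concentration of a unit-slope curve (molar).

    sabre (n = 1)       : EC50 = Kd / (q*eps*gamma - q*eps + 1)
    operational (n = 1) : EC50 = Kd / (1 + tau)
    hill                : EC50 = 10^logEC50 (any slope)
    """
    if model == "hill":
        return params.EC50
    if model == "sabre":
        if abs(params.n - 1.0) > 1e-9:
            raise ValidationError("closed-form SABRE EC50 requires n = 1")
        return params.Kd / (params.q * params.epsilon * params.gamma
                            - params.q * params.epsilon + 1.0)
    if model == "operational":
        if abs(params.n - 1.0) > 1e-9:
            raise ValidationError("closed-form operational EC50 requires n = 1")
        return params.Kd / (1.0 + params.tau)
    raise ValidationError(f"unknown model {model!r}")
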