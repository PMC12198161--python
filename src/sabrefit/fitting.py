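"""Global nonlinear least squares with shared, fixed and per-dataset
parameters.

This is the core of the pipeline: several concentration-effect datasets are
fitted simultaneously, with each model parameter resolved to a named
:class:`ParameterSpec` that is either fixed, free for one dataset, or free
and shared by a group of datasets. Residuals are pooled on the fractional
effect scale and unweighted (the study fits mean curves).

Four named strategies mirror the sharing/constraint schemes used for the
SABRE model on a 3-agonist x (naive, inactivated) study:

1. all six curves at once — gain ``gamma`` shared everywhere, operable
   fraction ``q`` shared among the inactivated ("X") curves, ``logKd`` free
   per curve;
2. naive curves only — ``gamma`` shared, ``logKd`` per curve;
3. one agonist's N/X pair at a time — ``gamma`` and ``logKd`` shared within
   the pair, ``q`` free on the X curve;
4. all six at once with each agonist's ``logKd`` fixed (taken from the
   strategy-3 pair fits) — only shared ``gamma`` and shared ``q`` remain.

Each strategy has an initial stage (``epsilon`` and ``n`` free, shared) and
a final stage where both are constrained to unity; the final stage is the
default. Scale parameters (``gamma``, ``tau``) are optimised on the log10
scale; ``logKd`` is the fitted quantity for binding affinity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import diagnostics
from .data import ECDataset
from .errors import ConfigurationError, FitFailureError, ValidationError
from .models import (HillParams, OperationalParams, SabreParams,
                     operational_fraction, sabre_fraction)
from .normalization import fit_hill

__all__ = [
    "ParameterSpec",
    "FitSpec",
    "ParamEstimate",
    "FitResult",
    "ModelComparison",
    "build_strategy",
    "fit_global",
    "fit_operational_pair",
    "compare_models",
]

MODEL_PARAM_NAMES = {
    "sabre": ("epsilon", "gamma", "n", "logKd", "q"),
    "operational": ("tau", "n", "logKd"),
}

# default bounds (natural scale) per model-parameter kind
_DEFAULT_BOUNDS = {
    "epsilon": (1e-6, 1.0),
    "gamma": (1e-3, 1e6),
    "tau": (1e-3, 1e6),
    "n": (0.2, 5.0),
    "q": (1e-6, 1.0),
}

_LOG_SCALE_KINDS = ("gamma", "tau")


@dataclass(frozen=True)
class ParameterSpec:
    """One named parameter slot of a global fit.

    key      : unique identifier ("gamma", "logKd_NECA", "tau_X", ...)
    kind     : which model parameter it feeds (epsilon|gamma|n|logKd|q|tau)
    fixed    : constant value (natural scale) or None if free
    bounds   : (lo, hi) on the natural scale (free parameters only)
    initials : deterministic multi-start values, natural scale
    log10    : optimise on the log10 scale (gamma, tau)
    """

    key: str
    kind: str
    fixed: float | None = None
    bounds: tuple | None = None
    initials: tuple = ()
    log10: bool = False

    def __post_init__(self):
        if self.kind not in ("epsilon", "gamma", "n", "logKd", "q", "tau"):
            raise ValidationError(f"unknown parameter kind {self.kind!r}")
        if self.fixed is None:
            if self.bounds is None or not self.initials:
                raise ValidationError(
                    f"free parameter {self.key!r} needs bounds and initials")

    def to_internal(self, v: float) -> float:
        return math.log10(v) if self.log10 else v

    def to_natural(self, v: float) -> float:
        return 10.0 ** v if self.log10 else v


@dataclass
class FitSpec:
    """Datasets + model assignment + parameter map for one global fit."""

    datasets: list  # of ECDataset
    models: list  # 'sabre' | 'operational', aligned with datasets
    param_maps: list  # per dataset: model parameter name -> ParameterSpec key
    specs: dict  # key -> ParameterSpec
    strategy: str | int | None = None
    stage: str = "final"

    def __post_init__(self):
        if not self.datasets:
            raise ValidationError("FitSpec requires at least one dataset")
        if not (len(self.datasets) == len(self.models) == len(self.param_maps)):
            raise ValidationError("datasets, models and param_maps must align")
        for ds, model, pmap in zip(self.datasets, self.models, self.param_maps):
            if model not in MODEL_PARAM_NAMES:
                raise ValidationError(f"unknown model {model!r}")
            for pname in MODEL_PARAM_NAMES[model]:
                if pname not in pmap:
                    raise ValidationError(
                        f"{ds.name}: model parameter {pname!r} is unmapped")
                key = pmap[pname]
                if key not in self.specs:
                    raise ValidationError(f"{ds.name}: unknown parameter key {key!r}")
                if self.specs[key].kind != pname:
                    raise ValidationError(
                        f"{ds.name}: key {key!r} has kind {self.specs[key].kind!r}, "
                        f"expected {pname!r}")
            if model == "sabre" and ds.pretreatment == "N":
                qspec = self.specs[pmap["q"]]
                if qspec.fixed != 1.0:
                    raise ValidationError(
                        f"{ds.name}: q must be fixed at 1 on naive datasets "
                        "(a free q may only attach to X datasets)")

    @property
    def free_keys(self) -> list:
        return [k for k, s in self.specs.items() if s.fixed is None]


@dataclass(frozen=True)
class ParamEstimate:
    value: float
    ci: tuple | None = None  # (lo | None, hi | None); None side = open ("?")
    dependency: float | None = None


@dataclass
class FitResult:
    params: dict  # free key -> ParamEstimate (natural scale)
    fixed: dict  # fixed key -> value
    ss: float
    n_obs: int
    n_free: int
    r2_per_dataset: dict
    r2_global: float
    r2_adjusted: float
    aicc: float
    ambiguous: bool
    dependency_report: object
    strategy: str | int | None
    convergence: dict
    free_keys: list = field(default_factory=list)
    _problem: object = field(default=None, repr=False)
    _x: np.ndarray = field(default=None, repr=False)
    _jac: np.ndarray = field(default=None, repr=False)

    def __getitem__(self, key: str) -> float:
        if key in self.params:
            return self.params[key].value
        return self.fixed[key]


class _Problem:
    """Evaluation machinery shared by the fit, profiles and bands."""

    # convergence protocol: 1e-10 relative SS change, bounded iteration count
    _LS_OPTS = dict(method="trf", ftol=1e-10, xtol=1e-12, gtol=1e-12)

    def __init__(self, spec: FitSpec):
        self.spec = spec
        self.free_keys = spec.free_keys
        self._index = {k: i for i, k in enumerate(self.free_keys)}
        self.internal_bounds = []
        starts = []
        for k in self.free_keys:
            s = spec.specs[k]
            lo, hi = (s.to_internal(b) for b in s.bounds)
            self.internal_bounds.append((lo, hi))
            starts.append([float(np.clip(s.to_internal(v), lo, hi))
                           for v in s.initials])
        self.x0s = [np.array(combo) for combo in itertools.product(*starts)]
        self._y = np.concatenate([ds.fractions for ds in spec.datasets])

    # -- parameter resolution -------------------------------------------
    def _value(self, key: str, x: np.ndarray, fixed_override: dict) -> float:
        s = self.spec.specs[key]
        if s.fixed is not None:
            return s.fixed
        if key in fixed_override:
            return s.to_natural(fixed_override[key])
        return s.to_natural(x[self._index[key]])

    def model_fraction(self, i: int, x: np.ndarray, c=None,
                       fixed_override: dict | None = None) -> np.ndarray:
        fixed_override = fixed_override or {}
        ds = self.spec.datasets[i]
        pmap = self.spec.param_maps[i]
        model = self.spec.models[i]
        if c is None:
            c = ds.concentrations
        get = lambda name: self._value(pmap[name], x, fixed_override)
        if model == "sabre":
            p = SabreParams(epsilon=get("epsilon"), gamma=get("gamma"),
                            n=get("n"), logKd=get("logKd"), q=get("q"))
            return np.atleast_1d(sabre_fraction(c, p))
        p = OperationalParams(tau=get("tau"), n=get("n"), logKd=get("logKd"))
        return np.atleast_1d(operational_fraction(c, p))

    def residual(self, x: np.ndarray, fixed_override: dict | None = None,
                 free_mask=None, x_full=None) -> np.ndarray:
        if free_mask is not None:
            xf = x_full.copy()
            xf[free_mask] = x
            x = xf
        pred = np.concatenate([
            self.model_fraction(i, x, fixed_override=fixed_override)
            for i in range(len(self.spec.datasets))
        ])
        return pred - self._y

    # -- optimisation ----------------------------------------------------
    def solve(self, x0: np.ndarray, fixed_override: dict | None = None):
        fixed_override = fixed_override or {}
        mask = np.array([k not in fixed_override for k in self.free_keys])
        x_full = x0.copy()
        for k, v in fixed_override.items():
            x_full[self._index[k]] = v
        if not mask.any():  # nothing left to optimise
            ss = float(np.sum(self.residual(x_full) ** 2))
            return x_full, ss, None
        lo = np.array([b[0] for b, m in zip(self.internal_bounds, mask) if m])
        hi = np.array([b[1] for b, m in zip(self.internal_bounds, mask) if m])
        x0_sub = np.clip(x_full[mask], lo, hi)
        max_nfev = 2000 * (mask.sum() + 1)
        sol = least_squares(
            self.residual, x0_sub, bounds=(lo, hi), max_nfev=max_nfev,
            kwargs=dict(fixed_override=fixed_override, free_mask=mask,
                        x_full=x_full),
            **self._LS_OPTS)
        x_out = x_full.copy()
        x_out[mask] = sol.x
        return x_out, 2.0 * float(sol.cost), sol

    def solve_fixed(self, fixed_override: dict, warm: np.ndarray):
        """Re-optimise all free parameters except those pinned; returns (x, ss)."""
        x, ss, _ = self.solve(warm, fixed_override=fixed_override)
        return x, ss


def fit_global(spec: FitSpec, compute_ci: bool = False,
               ci_level: float = 0.95) -> FitResult:
    """Fit a :class:`FitSpec` by pooled, unweighted least squares.

    Deterministic multi-start (the cartesian product of each free
    parameter's listed initials); the start with the lowest residual sum of
    squares wins, ties broken by start order. A rank-deficient solution is
    flagged ambiguous rather than raised.
    """
    problem = _Problem(spec)
    n_free = len(problem.free_keys)
    n_obs = sum(len(ds.concentrations) for ds in spec.datasets)
    if n_obs <= n_free:
        raise ValidationError("fewer pooled observations than free parameters")

    best = None
    attempts = []
    for x0 in problem.x0s:
        x, ss, sol = problem.solve(x0)
        attempts.append({"x0": list(x0), "ss": ss,
                         "status": None if sol is None else sol.status})
        if sol is not None and sol.status <= 0:
            continue
        if best is None or ss < best[1] - 1e-15 * max(1.0, best[1]):
            best = (x, ss, sol)
    if best is None:
        raise FitFailureError("global fit did not converge from any start",
                              details=attempts)
    x, ss, sol = best
    jac = sol.jac if sol is not None else None

    # goodness of fit on the fractional scale
    r2_per = {}
    pooled_pred = []
    for i, ds in enumerate(spec.datasets):
        pred = problem.model_fraction(i, x)
        pooled_pred.append(pred)
        try:
            r2_per[ds.name] = diagnostics.r_squared(ds.fractions, pred)
        except ValidationError:
            r2_per[ds.name] = float("nan")
    pooled_pred = np.concatenate(pooled_pred)
    pooled_obs = np.concatenate([ds.fractions for ds in spec.datasets])
    r2_global = diagnostics.r_squared(pooled_obs, pooled_pred)
    r2_adj = diagnostics.adjusted_r_squared(r2_global, n_obs, n_free)
    try:
        aicc_value = diagnostics.aicc(max(ss, 1e-300), n_obs, n_free)
    except ValidationError:
        aicc_value = float("nan")

    if jac is not None and n_free >= 1:
        deps = diagnostics.dependency_from_jacobian(jac)
    else:
        deps = np.ones(n_free)
    dep_values = dict(zip(problem.free_keys, deps))
    dep_report = diagnostics.DependencyReport(
        dep_values,
        {k: diagnostics.classify_dependency(v) for k, v in dep_values.items()})
    ambiguous = dep_report.ambiguous

    params = {}
    for k in problem.free_keys:
        s = spec.specs[k]
        params[k] = ParamEstimate(value=s.to_natural(x[problem._index[k]]),
                                  dependency=dep_values[k])
    fixed = {k: s.fixed for k, s in spec.specs.items() if s.fixed is not None}

    result = FitResult(
        params=params, fixed=fixed, ss=ss, n_obs=n_obs, n_free=n_free,
        r2_per_dataset=r2_per, r2_global=r2_global, r2_adjusted=r2_adj,
        aicc=aicc_value, ambiguous=ambiguous, dependency_report=dep_report,
        strategy=spec.strategy,
        convergence={"n_starts": len(problem.x0s), "attempts": attempts,
                     "nfev": None if sol is None else sol.nfev},
        free_keys=list(problem.free_keys),
        _problem=problem, _x=x, _jac=jac,
    )
    if compute_ci:
        for k in result.free_keys:
            lo, hi = diagnostics.profile_ci(result, k, level=ci_level)
            result.params[k] = ParamEstimate(
                value=result.params[k].value, ci=(lo, hi),
                dependency=result.params[k].dependency)
    return result


# ------------------------------------------------------------- strategies

def _group_by_agonist(datasets):
    groups: dict = {}
    for ds in datasets:
        slot = groups.setdefault(ds.agonist, {})
        if ds.pretreatment in slot:
            raise ValidationError(f"duplicate dataset {ds.name}")
        slot[ds.pretreatment] = ds
    return groups


def _logkd_bounds(datasets) -> tuple:
    logc = np.concatenate([
        np.log10(ds.concentrations[ds.concentrations > 0]) for ds in datasets])
    return (float(logc.min()) - 3.0, float(logc.max()) + 3.0)


def _logkd_initial(naive_ds: ECDataset) -> float:
    """logKd starts at the Hill-fit logEC50 of the naive curve."""
    try:
        return fit_hill(naive_ds).params.logEC50
    except (FitFailureError, ValidationError):
        logc = np.log10(naive_ds.concentrations[naive_ds.concentrations > 0])
        return float(logc.mean())


def _shared_specs(stage: str) -> dict:
    """epsilon and n specs for the requested stage."""
    if stage == "final":
        eps = ParameterSpec("epsilon", "epsilon", fixed=1.0)
        n = ParameterSpec("n", "n", fixed=1.0)
    elif stage == "initial":
        eps = ParameterSpec("epsilon", "epsilon",
                            bounds=_DEFAULT_BOUNDS["epsilon"], initials=(0.5,))
        n = ParameterSpec("n", "n", bounds=_DEFAULT_BOUNDS["n"], initials=(1.0,))
    else:
        raise ConfigurationError(f"unknown stage {stage!r}")
    return {"epsilon": eps, "n": n}


_Q_NAIVE = ParameterSpec("q_naive", "q", fixed=1.0)


def _gamma_spec(key="gamma") -> ParameterSpec:
    return ParameterSpec(key, "gamma", bounds=_DEFAULT_BOUNDS["gamma"],
                         initials=(1.0, 100.0), log10=True)


def _q_spec(key="q") -> ParameterSpec:
    return ParameterSpec(key, "q", bounds=_DEFAULT_BOUNDS["q"], initials=(0.5,))


def build_strategy(datasets, strategy, stage: str = "final",
                   logkd_values: dict | None = None):
    """Construct the FitSpec(s) of one of the four SABRE fitting strategies.

    Returns a single :class:`FitSpec` for strategies 1, 2 and 4, and a list
    of per-agonist FitSpecs for strategy 3. ``stage`` selects the initial
    (epsilon, n free and shared) or final (epsilon = n = 1) regression;
    strategy 4 additionally needs ``logkd_values`` mapping each agonist to
    the logKd obtained from the strategy-3 pair fits.
    """
    datasets = list(datasets)
    if strategy not in (1, 2, 3, 4):
        raise ConfigurationError(f"unknown strategy {strategy!r}")
    groups = _group_by_agonist(datasets)
    kd_bounds = _logkd_bounds(datasets)

    if strategy == 2:
        if any(ds.pretreatment == "X" for ds in datasets):
            raise ConfigurationError("strategy 2 uses only the naive (N) datasets")
        specs = dict(**{s.key: s for s in _shared_specs(stage).values()})
        specs["gamma"] = _gamma_spec()
        specs[_Q_NAIVE.key] = _Q_NAIVE
        maps = []
        for ds in datasets:
            key = f"logKd_{ds.agonist}_{ds.pretreatment}"
            specs[key] = ParameterSpec(key, "logKd", bounds=kd_bounds,
                                       initials=(_logkd_initial(ds),))
            maps.append({"epsilon": "epsilon", "n": "n", "gamma": "gamma",
                         "logKd": key, "q": _Q_NAIVE.key})
        return FitSpec(datasets, ["sabre"] * len(datasets), maps, specs,
                       strategy=2, stage=stage)

    if strategy == 3:
        out = []
        for agonist, slot in groups.items():
            if set(slot) != {"N", "X"}:
                raise ConfigurationError(
                    f"strategy 3 needs an N/X pair for {agonist}")
            pair = [slot["N"], slot["X"]]
            specs = dict(**{s.key: s for s in _shared_specs(stage).values()})
            specs["gamma"] = _gamma_spec()
            kd_key = f"logKd_{agonist}"
            specs[kd_key] = ParameterSpec(kd_key, "logKd", bounds=kd_bounds,
                                          initials=(_logkd_initial(slot["N"]),))
            q_key = f"q_{agonist}"
            specs[q_key] = _q_spec(q_key)
            specs[_Q_NAIVE.key] = _Q_NAIVE
            maps = [
                {"epsilon": "epsilon", "n": "n", "gamma": "gamma",
                 "logKd": kd_key, "q": _Q_NAIVE.key},
                {"epsilon": "epsilon", "n": "n", "gamma": "gamma",
                 "logKd": kd_key, "q": q_key},
            ]
            out.append(FitSpec(pair, ["sabre", "sabre"], maps, specs,
                               strategy=3, stage=stage))
        return out

    # strategies 1 and 4: the full six-dataset arrangement
    for agonist, slot in groups.items():
        if set(slot) != {"N", "X"}:
            raise ConfigurationError(
                f"strategy {strategy} needs both N and X datasets for {agonist}")
    if strategy == 4 and (logkd_values is None
                          or any(a not in logkd_values for a in groups)):
        raise ConfigurationError(
            "strategy 4 requires a logKd value for every agonist "
            "(taken from the strategy-3 pair fits)")

    specs = dict(**{s.key: s for s in _shared_specs(stage).values()})
    specs["gamma"] = _gamma_spec()
    specs["q"] = _q_spec()  # shared among the X datasets only
    specs[_Q_NAIVE.key] = _Q_NAIVE
    maps, models = [], []
    for ds in datasets:
        if strategy == 1:
            kd_key = f"logKd_{ds.agonist}_{ds.pretreatment}"
            specs[kd_key] = ParameterSpec(kd_key, "logKd", bounds=kd_bounds,
                                          initials=(_logkd_initial(
                                              groups[ds.agonist]["N"]),))
        else:  # strategy 4: per-agonist logKd, fixed
            kd_key = f"logKd_{ds.agonist}"
            specs[kd_key] = ParameterSpec(kd_key, "logKd",
                                          fixed=float(logkd_values[ds.agonist]))
        maps.append({"epsilon": "epsilon", "n": "n", "gamma": "gamma",
                     "logKd": kd_key,
                     "q": "q" if ds.pretreatment == "X" else _Q_NAIVE.key})
        models.append("sabre")
    return FitSpec(datasets, models, maps, specs, strategy=strategy, stage=stage)


def build_single_curve_spec(ds: ECDataset,
                            free=("epsilon", "gamma", "logKd"),
                            n_value: float = 1.0) -> FitSpec:
    """Single-curve SABRE FitSpec with a chosen set of free parameters.

    Used for identifiability experiments: with epsilon, gamma and logKd
    simultaneously free on one curve the fit sits on the epsilon*gamma
    ridge and every free parameter comes out redundant (dependency ~ 1).
    """
    kd_bounds = _logkd_bounds([ds])
    specs = {
        "n": ParameterSpec("n", "n", fixed=n_value),
        "q": (_q_spec("q") if ("q" in free and ds.pretreatment == "X")
              else ParameterSpec("q", "q", fixed=1.0)),
        "epsilon": (ParameterSpec("epsilon", "epsilon",
                                  bounds=_DEFAULT_BOUNDS["epsilon"],
                                  initials=(0.5,))
                    if "epsilon" in free
                    else ParameterSpec("epsilon", "epsilon", fixed=1.0)),
        "gamma": (_gamma_spec() if "gamma" in free
                  else ParameterSpec("gamma", "gamma", fixed=1.0)),
        "logKd": (ParameterSpec("logKd", "logKd", bounds=kd_bounds,
                                initials=(_logkd_initial(ds),))
                  if "logKd" in free
                  else ParameterSpec("logKd", "logKd",
                                     fixed=float(np.log10(
                                         ds.concentrations[
                                             ds.concentrations > 0]).mean()))),
    }
    pmap = {name: name for name in MODEL_PARAM_NAMES["sabre"]}
    return FitSpec([ds], ["sabre"], [pmap], specs, strategy="single")


# -------------------------------------------------- operational model fit

def fit_operational_pair(pair, compute_ci: bool = False,
                         ci_level: float = 0.95) -> FitResult:
    """Operational-model global fit of one agonist's N/X dataset pair.

    n is constrained to unity, logKd is shared within the pair, and the
    operational efficacy tau is free per dataset (tau_N, tau_X).
    """
    pair = list(pair)
    if len(pair) != 2:
        raise ValidationError("operational pair fit requires exactly 2 datasets")
    if pair[0].agonist != pair[1].agonist:
        raise ValidationError("operational pair fit requires matching agonists")
    pres = {ds.pretreatment for ds in pair}
    if pres != {"N", "X"}:
        raise ValidationError("operational pair fit requires one N and one X dataset")
    naive = next(ds for ds in pair if ds.pretreatment == "N")
    kd_key = f"logKd_{naive.agonist}"
    specs = {
        "n": ParameterSpec("n", "n", fixed=1.0),
        kd_key: ParameterSpec(kd_key, "logKd", bounds=_logkd_bounds(pair),
                              initials=(_logkd_initial(naive),)),
    }
    maps = []
    for ds in pair:
        tau_key = f"tau_{ds.pretreatment}"
        specs[tau_key] = ParameterSpec(tau_key, "tau",
                                       bounds=_DEFAULT_BOUNDS["tau"],
                                       initials=(1.0, 100.0), log10=True)
        maps.append({"tau": tau_key, "n": "n", "logKd": kd_key})
    spec = FitSpec(pair, ["operational", "operational"], maps, specs,
                   strategy="operational")
    return fit_global(spec, compute_ci=compute_ci, ci_level=ci_level)


# ------------------------------------------------------- model comparison

@dataclass(frozen=True)
class ModelComparison:
    aicc: dict  # label -> AICc
    delta_aicc: dict  # label -> AICc - min AICc
    weights: dict  # label -> Akaike weight (fraction, sums to 1)


def compare_models(sabre: FitResult, operational: FitResult) -> ModelComparison:
    """AICc comparison of two fits to the identical observations."""
    if sabre.n_obs != operational.n_obs:
        raise ValidationError(
            "model comparison requires identical observation counts")
    labels = ("sabre", "operational")
    values = np.array([sabre.aicc, operational.aicc])
    w = diagnostics.akaike_weights(values)
    return ModelComparison(
        aicc=dict(zip(labels, map(float, values))),
        delta_aicc=dict(zip(labels, map(float, values - values.min()))),
        weights=dict(zip(labels, map(float, w))),
    )
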