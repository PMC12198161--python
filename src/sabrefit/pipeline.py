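"""End-to-end orchestration: normalize -> global fits -> diagnostics ->
model comparison, with JSON/CSV/log outputs.

Open confidence-interval sides are serialized as JSON ``null`` and
rendered "?" in tables. The log records, for every fit, the free-parameter
count and the dataset -> parameter-key sharing map, since the sharing
bookkeeping is the main reproducibility hazard of this kind of analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, EstimationError
from .fitting import (FitResult, build_strategy, compare_models, fit_global,
                      fit_operational_pair)
from .furchgott import equieffective_pairs, furchgott_regression
from .normalization import fit_hill, normalize_study

__all__ = ["RunConfig", "run_pipeline", "fit_result_to_dict"]

RESULT_SCHEMA_VERSION = 1

_KNOWN_STEPS = {"1", "2", "3", "4", "operational", "furchgott"}


@dataclass
class RunConfig:
    strategies: tuple = ("3", "4", "operational")
    stage: str = "final"  # 'final' fixes epsilon = n = 1
    logkd_values: dict | None = None  # strategy 4; defaults to strategy-3 output
    ci_level: float = 0.95
    compute_ci: bool = True
    normalize: bool = True
    outdir: str | Path | None = None
    verbose: bool = False

    def __post_init__(self):
        self.strategies = tuple(str(s) for s in self.strategies)
        unknown = set(self.strategies) - _KNOWN_STEPS
        if unknown:
            raise ConfigurationError(f"unknown pipeline step(s): {sorted(unknown)}")
        if "4" in self.strategies and self.logkd_values is None \
                and "3" not in self.strategies:
            raise ConfigurationError(
                "strategy 4 needs logKd values: supply logkd_values or run "
                "strategy 3 in the same pipeline")


def _ci_display(ci) -> str:
    if ci is None:
        return ""
    lo, hi = ci
    fmt = lambda v: "?" if v is None else f"{v:.4g}"
    return f"{fmt(lo)} to {fmt(hi)}"


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "strategy": fit.strategy,
        "params": {
            k: {"value": est.value,
                "ci": None if est.ci is None else [est.ci[0], est.ci[1]],
                "ci_display": _ci_display(est.ci),
                "dependency": est.dependency,
                "classification": fit.dependency_report.classifications[k]}
            for k, est in fit.params.items()
        },
        "fixed": fit.fixed,
        "ss": fit.ss,
        "n_obs": fit.n_obs,
        "n_free": fit.n_free,
        "r2_per_dataset": fit.r2_per_dataset,
        "r2_global": fit.r2_global,
        "r2_adjusted": fit.r2_adjusted,
        "aicc": fit.aicc,
        "ambiguous": fit.ambiguous,
    }


def _param_rows(label: str, fit: FitResult) -> list:
    rows = []
    for k, est in fit.params.items():
        rows.append({"fit": label, "parameter": k, "value": est.value,
                     "ci": _ci_display(est.ci), "dependency": est.dependency,
                     "fixed": False})
    for k, v in fit.fixed.items():
        rows.append({"fit": label, "parameter": k, "value": v, "ci": "",
                     "dependency": None, "fixed": True})
    return rows


def _log_fit(log: list, label: str, fit: FitResult) -> None:
    sharing = {ds.name: pmap for ds, pmap in
               zip(fit._problem.spec.datasets, fit._problem.spec.param_maps)}
    log.append(f"[{label}] n_free={fit.n_free} n_obs={fit.n_obs} "
               f"ss={fit.ss:.6g} ambiguous={fit.ambiguous} sharing={sharing}")


def run_pipeline(config: RunConfig, datasets) -> dict:
    """Run the configured steps over a study; returns the result bundle.

    If ``config.outdir`` is set, writes ``results.json``, a flat
    ``parameters.csv`` and ``run.log`` there (partial outputs plus a
    manifest survive a failing stage).
    """
    log: list = []
    bundle: dict = {"schema_version": RESULT_SCHEMA_VERSION, "fits": {}}
    rows: list = []
    outdir = Path(config.outdir) if config.outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    try:
        if config.normalize:
            norm = normalize_study(datasets)
            datasets = norm.datasets
            bundle["normalization"] = {
                "system_emax": norm.system_emax,
                "hill_fits": {name: {"Emax": f.params.Emax,
                                     "logEC50": f.params.logEC50,
                                     "nH": f.params.nH, "rss": f.rss}
                              for name, f in norm.hill_fits.items()},
            }
            log.append(f"[normalize] system_emax={norm.system_emax:.4f}")

        pair_groups: dict = {}
        for ds in datasets:
            pair_groups.setdefault(ds.agonist, {})[ds.pretreatment] = ds

        sabre_pair_fits: dict = {}
        if "3" in config.strategies:
            for spec in build_strategy(datasets, 3, stage=config.stage):
                fit = fit_global(spec, compute_ci=config.compute_ci,
                                 ci_level=config.ci_level)
                agonist = spec.datasets[0].agonist
                sabre_pair_fits[agonist] = fit
                label = f"strategy3_{agonist}"
                bundle["fits"][label] = fit_result_to_dict(fit)
                rows += _param_rows(label, fit)
                _log_fit(log, label, fit)

        for s in ("1", "2"):
            if s in config.strategies:
                data = (datasets if s == "1"
                        else [d for d in datasets if d.pretreatment == "N"])
                spec = build_strategy(data, int(s), stage=config.stage)
                fit = fit_global(spec, compute_ci=config.compute_ci,
                                 ci_level=config.ci_level)
                label = f"strategy{s}"
                bundle["fits"][label] = fit_result_to_dict(fit)
                rows += _param_rows(label, fit)
                _log_fit(log, label, fit)

        if "4" in config.strategies:
            logkd = config.logkd_values
            if logkd is None:
                logkd = {a: f[f"logKd_{a}"] for a, f in sabre_pair_fits.items()}
                log.append(f"[strategy4] logKd taken from strategy 3: {logkd}")
            spec = build_strategy(datasets, 4, stage=config.stage,
                                  logkd_values=logkd)
            fit = fit_global(spec, compute_ci=config.compute_ci,
                             ci_level=config.ci_level)
            bundle["fits"]["strategy4"] = fit_result_to_dict(fit)
            rows += _param_rows("strategy4", fit)
            _log_fit(log, "strategy4", fit)

        if "operational" in config.strategies:
            bundle["model_comparison"] = {}
            for agonist, slot in pair_groups.items():
                if set(slot) != {"N", "X"}:
                    continue
                fit = fit_operational_pair([slot["N"], slot["X"]],
                                           compute_ci=config.compute_ci,
                                           ci_level=config.ci_level)
                label = f"operational_{agonist}"
                bundle["fits"][label] = fit_result_to_dict(fit)
                rows += _param_rows(label, fit)
                _log_fit(log, label, fit)
                if agonist in sabre_pair_fits:
                    cmp_ = compare_models(sabre_pair_fits[agonist], fit)
                    bundle["model_comparison"][agonist] = {
                        "aicc": cmp_.aicc,
                        "delta_aicc": cmp_.delta_aicc,
                        "relative_probability_pct": {
                            m: 100.0 * w for m, w in cmp_.weights.items()},
                    }
                    log.append(f"[compare_{agonist}] weights={cmp_.weights}")

        if "furchgott" in config.strategies:
            bundle["furchgott"] = {}
            for agonist, slot in pair_groups.items():
                if set(slot) != {"N", "X"}:
                    continue
                hn = fit_hill(slot["N"]).params
                hx = fit_hill(slot["X"]).params
                try:
                    res = furchgott_regression(equieffective_pairs(hn, hx))
                except EstimationError as exc:
                    # double-reciprocal regression is leverage-dominated and
                    # can fail per agonist under noise; record, don't abort
                    bundle["furchgott"][agonist] = {"error": str(exc)}
                    log.append(f"[furchgott_{agonist}] estimation failed: {exc}")
                    continue
                bundle["furchgott"][agonist] = {
                    "q": res.q, "Kd_M": res.Kd, "logKd": res.logKd,
                    "slope": res.slope, "intercept": res.intercept,
                    "r_squared": res.r_squared, "n_pairs": res.n_pairs,
                    "pairs_from": "fitted Hill curves",
                }
                log.append(f"[furchgott_{agonist}] q={res.q:.4f} "
                           f"logKd={res.logKd:.4f}")
    except Exception as exc:
        log.append(f"[error] {type(exc).__name__}: {exc}")
        if outdir is not None:
            _write_outputs(outdir, bundle, rows, log, complete=False)
        raise

    bundle["log"] = log
    if outdir is not None:
        _write_outputs(outdir, bundle, rows, log, complete=True)
    if config.verbose:
        print("\n".join(log))
    return bundle


def _write_outputs(outdir: Path, bundle: dict, rows: list, log: list,
                   complete: bool) -> None:
    with open(outdir / "results.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=float)
    if rows:
        pd.DataFrame(rows).to_csv(outdir / "parameters.csv", index=False)
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(
        {"complete": complete,
         "files": ["results.json", "parameters.csv", "run.log"]}))
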