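"""ECTable CSV dialect: reading and writing concentration-effect tables.

Columns: ``agonist`` (string), ``pretreatment`` (N|X), ``conc_M`` (float,
molar), ``effect_pct`` (float, percent of system maximum), and optionally
``sem_pct`` and ``n_reps``. One row per (agonist, pretreatment,
concentration); rows are grouped into :class:`~sabrefit.data.ECDataset`
objects sorted by concentration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import ECDataset
from .errors import ValidationError

__all__ = ["read_ec_table", "write_ec_table", "datasets_to_frame"]

_REQUIRED = ("agonist", "pretreatment", "conc_M", "effect_pct")
_OPTIONAL = ("sem_pct", "n_reps")


def read_ec_table(path) -> list:
    """Read an ECTable CSV into a list of ECDatasets (file order)."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    if df["conc_M"].isna().any() or (df["conc_M"] <= 0).any():
        bad = df.index[df["conc_M"].isna() | (df["conc_M"] <= 0)] + 2  # header+1-based
        raise ValidationError(f"{path}: non-positive conc_M at row(s) {list(bad)}")

    datasets = []
    seen = []
    for (agonist, pre), grp in df.groupby(["agonist", "pretreatment"], sort=False):
        seen.append((agonist, pre))
        dup = grp["conc_M"].duplicated()
        if dup.any():
            rows = list(grp.index[dup] + 2)
            raise ValidationError(
                f"{path}: duplicate concentration for {agonist} {pre} at row(s) {rows}")
        grp = grp.sort_values("conc_M")
        datasets.append(ECDataset(
            agonist=str(agonist),
            pretreatment=str(pre),
            concentrations=grp["conc_M"].to_numpy(),
            effects=grp["effect_pct"].to_numpy(),
            sems=grp["sem_pct"].to_numpy() if "sem_pct" in grp
                 and grp["sem_pct"].notna().all() else None,
            n_reps=grp["n_reps"].to_numpy() if "n_reps" in grp
                   and grp["n_reps"].notna().all() else None,
        ))
    return datasets


def datasets_to_frame(datasets) -> pd.DataFrame:
    rows = []
    for ds in datasets:
        for j, c in enumerate(ds.concentrations):
            row = {"agonist": ds.agonist, "pretreatment": ds.pretreatment,
                   "conc_M": c, "effect_pct": ds.effects[j]}
            if ds.sems is not None:
                row["sem_pct"] = ds.sems[j]
            if ds.n_reps is not None:
                row["n_reps"] = int(ds.n_reps[j])
            rows.append(row)
    return pd.DataFrame(rows)


def write_ec_table(datasets, path) -> None:
    """Write ECDatasets as an ECTable CSV (round-trips with read_ec_table)."""
    datasets_to_frame(datasets).to_csv(path, index=False)
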