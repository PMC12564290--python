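"""Readers and writers for the on-disk cohort layout.

A cohort directory holds ``phenotypes.csv`` plus one tab-delimited ``.1D``
time-series file per subject per atlas named ``<SUB_ID>_<atlas>.1D`` (one
row per timepoint, one column per ROI, no header).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Cohort

__all__ = ["read_phenotypes", "read_timeseries", "read_cohort"]

_REQUIRED = ("SUB_ID", "SITE_ID", "AGE_AT_SCAN", "SEX", "DX_GROUP")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Typed phenotype table; extra columns are preserved but unused."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty phenotype file: {path}")
    table = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    bad_age = pd.to_numeric(table["AGE_AT_SCAN"], errors="coerce").isna()
    if bad_age.any():
        row = int(np.flatnonzero(bad_age)[0])
        raise ValueError(f"non-numeric AGE_AT_SCAN at row {row}")
    table["AGE_AT_SCAN"] = table["AGE_AT_SCAN"].astype(float)
    table["SUB_ID"] = table["SUB_ID"].astype(int)
    table["SITE_ID"] = table["SITE_ID"].astype(str)
    dx = table["DX_GROUP"].astype(int)
    if not dx.isin((0, 1)).all():
        # ABIDE convention codes 1 = case, 2 = control
        if dx.isin((1, 2)).all():
            dx = (dx == 1).astype(int)
        else:
            raise ValueError("DX_GROUP must be coded {0,1} or {1,2}")
    table["DX_GROUP"] = dx
    return table


def read_timeseries(path: str | Path) -> np.ndarray:
    """T x M matrix from whitespace/tab-delimited text; ragged rows are
    rejected with the offending line number."""
    path = Path(path)
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            try:
                row = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(row)} columns, "
                    f"expected {width})"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"empty time-series file: {path}")
    return np.asarray(rows, dtype=np.float64)


def read_cohort(directory: str | Path) -> Cohort:
    """Load a written cohort back; atlas names are discovered from the
    ``<SUB_ID>_<atlas>.1D`` filename pattern."""
    directory = Path(directory)
    table = read_phenotypes(directory / "phenotypes.csv")
    pattern = re.compile(r"^(\d+)_(.+)\.1D$")
    atlas_names: set[str] = set()
    for f in directory.glob("*.1D"):
        match = pattern.match(f.name)
        if match:
            atlas_names.add(match.group(2))
    if not atlas_names:
        raise ValueError(f"no .1D time-series files found in {directory}")
    names = sorted(atlas_names)
    series: dict[tuple[int, str], np.ndarray] = {}
    for sub in table["SUB_ID"]:
        for name in names:
            path = directory / f"{int(sub)}_{name}.1D"
            if not path.exists():
                raise FileNotFoundError(
                    f"missing time series for subject {int(sub)}, atlas {name}"
                )
            series[(int(sub), name)] = read_timeseries(path)
    return Cohort(phenotypes=table, timeseries=series, atlas_names=names)
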