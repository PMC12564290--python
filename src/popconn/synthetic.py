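"""Synthetic multi-site, multi-atlas rs-fMRI-like cohorts with planted effects.

The generator emulates the structure of multi-site autism-imaging cohorts:
per-subject ROI time series under several parcellations ("atlases"), a
phenotype table with site/age/sex/diagnosis columns, site-level batch
structure, and a class-dependent increase in coupling on chosen ROI pairs.

A latent-factor model is used so that every derived functional-connectivity
matrix is a valid correlation matrix by construction:

    x[t, r] = eps[t, r] + w_g * g[t] + a_site[r] * u[t]
              + effect_size * sum_{pairs containing r, cases only} e_p[t]

with ``g`` a global factor shared by all ROIs (baseline connectivity),
``u`` a subject-specific factor whose ROI loadings ``a_site`` are shared by
all subjects of a site (site-correlated FC structure), ``e_p`` a factor
loading only on the two ROIs of a planted effect pair, and ``eps`` white
noise.  Cases and controls differ only through the pair factors, so
``effect_size = 0`` is an exact null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import rng_for

__all__ = [
    "CohortSpec",
    "Cohort",
    "generate_phenotypes",
    "generate_subject_timeseries",
    "generate_cohort",
    "write_cohort",
]

_GLOBAL_LOADING = 0.5
_AGE_BOUNDS = (6.0, 45.0)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``effect_pairs`` lists ``(atlas_index, (roi_i, roi_j))`` tuples carrying
    class signal: cases receive an extra shared latent of weight
    ``effect_size`` on both ROIs of each pair.
    """

    n_subjects: int = 150
    n_sites: int = 4
    atlas_sizes: tuple[int, ...] = (10, 12, 16)
    n_timepoints: int = 150
    effect_pairs: tuple[tuple[int, tuple[int, int]], ...] = (
        (0, (2, 5)), (0, (1, 7)), (0, (3, 8)),
        (1, (0, 4)), (1, (6, 9)), (1, (2, 11)),
        (2, (3, 12)), (2, (5, 9)), (2, (1, 14)),
    )
    effect_size: float = 1.0
    site_effect_sd: float = 0.3
    age_mean_range: tuple[float, float] = (12.0, 26.0)
    age_sd: float = 5.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 2 * self.n_sites:
            raise ValueError(
                f"n_subjects ({self.n_subjects}) must be >= 2 * n_sites "
                f"({self.n_sites})"
            )
        if self.n_timepoints < 3:
            raise ValueError(f"n_timepoints must be >= 3, got {self.n_timepoints}")
        if not self.atlas_sizes or any(m < 2 for m in self.atlas_sizes):
            raise ValueError(f"atlas_sizes entries must be >= 2, got {self.atlas_sizes}")
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError(f"class_balance must be in (0, 1), got {self.class_balance}")
        for a, (i, j) in self.effect_pairs:
            if not 0 <= a < len(self.atlas_sizes):
                raise ValueError(f"effect_pairs: atlas index {a} out of range")
            m = self.atlas_sizes[a]
            if not (0 <= i < m and 0 <= j < m and i != j):
                raise ValueError(
                    f"effect_pairs: ROI pair ({i}, {j}) invalid for atlas of size {m}"
                )

    @property
    def atlas_names(self) -> list[str]:
        return [f"atlas{i}" for i in range(len(self.atlas_sizes))]

    def with_effect_size(self, effect_size: float) -> "CohortSpec":
        from dataclasses import replace

        return replace(self, effect_size=effect_size)

    @classmethod
    def null(cls, seed: int = 0, **kwargs) -> "CohortSpec":
        """Same cohort structure with all class signal removed."""
        return cls(effect_size=0.0, seed=seed, **kwargs)


@dataclass
class Cohort:
    phenotypes: pd.DataFrame
    timeseries: dict[tuple[int, str], np.ndarray]  # (SUB_ID, atlas name) -> T x M
    atlas_names: list[str]
    spec: CohortSpec | None = None


def generate_phenotypes(spec: CohortSpec) -> pd.DataFrame:
    """One phenotype row per subject, fully determined by ``spec.seed``.

    Columns follow the multi-site convention: SUB_ID, SITE_ID, AGE_AT_SCAN,
    SEX (1 = male, 2 = female, drawn at the ~0.85 male skew typical of
    autism cohorts), DX_GROUP (1 = case, 0 = control), plus eye status,
    handedness and full-scale IQ extras.
    """
    spec.validate()
    rng = rng_for(spec.seed, "phenotypes")
    n = spec.n_subjects
    sites = np.array([f"SITE{i:02d}" for i in range(spec.n_sites)])
    # round-robin then shuffle: every site is populated
    site_idx = rng.permutation(np.arange(n) % spec.n_sites)
    age_means = rng.uniform(*spec.age_mean_range, size=spec.n_sites)
    ages = np.clip(
        rng.normal(age_means[site_idx], spec.age_sd), *_AGE_BOUNDS
    ).round(1)
    labels = (rng.random(n) < spec.class_balance).astype(int)
    sex = np.where(rng.random(n) < 0.85, 1, 2)
    fiq = np.round(rng.normal(105.0, 15.0, size=n) - 3.0 * labels, 1)
    return pd.DataFrame(
        {
            "SUB_ID": 50000 + np.arange(n),
            "SITE_ID": sites[site_idx],
            "AGE_AT_SCAN": ages,
            "SEX": sex,
            "DX_GROUP": labels,
            "EYE_STATUS_AT_SCAN": np.where(rng.random(n) < 0.7, 1, 2),
            "HANDEDNESS_CATEGORY": np.where(rng.random(n) < 0.9, "R", "L"),
            "FIQ": fiq,
        }
    )


def generate_subject_timeseries(
    row: pd.Series | dict, atlas_index: int, spec: CohortSpec
) -> np.ndarray:
    """T x M BOLD-like matrix for one subject under one atlas.

    Deterministic given ``(spec.seed, SUB_ID, atlas_index)``; site loading
    vectors are shared across subjects of a site so FC structure is
    site-correlated.
    """
    spec.validate()
    if not 0 <= atlas_index < len(spec.atlas_sizes):
        raise ValueError(f"atlas_index {atlas_index} out of range")
    m = spec.atlas_sizes[atlas_index]
    t = spec.n_timepoints
    sub_id = int(row["SUB_ID"])
    rng = rng_for(spec.seed, "ts", sub_id, atlas_index)
    site_rng = rng_for(spec.seed, "site", str(row["SITE_ID"]), atlas_index)
    site_loadings = site_rng.standard_normal(m) * spec.site_effect_sd

    x = rng.standard_normal((t, m))
    x += _GLOBAL_LOADING * rng.standard_normal((t, 1))
    x += rng.standard_normal((t, 1)) * site_loadings[None, :]
    if int(row["DX_GROUP"]) == 1 and spec.effect_size > 0:
        for a, (i, j) in spec.effect_pairs:
            if a != atlas_index:
                continue
            e = rng.standard_normal((t, 1)) * spec.effect_size
            x[:, [i, j]] += e
    else:
        # keep the subject RNG stream aligned between cases and controls
        for a, _ in spec.effect_pairs:
            if a == atlas_index:
                rng.standard_normal((t, 1))
    return x


def generate_cohort(spec: CohortSpec) -> Cohort:
    phenotypes = generate_phenotypes(spec)
    series: dict[tuple[int, str], np.ndarray] = {}
    for _, row in phenotypes.iterrows():
        for a, name in enumerate(spec.atlas_names):
            series[(int(row["SUB_ID"]), name)] = generate_subject_timeseries(
                row, a, spec
            )
    return Cohort(phenotypes=phenotypes, timeseries=series,
                  atlas_names=spec.atlas_names, spec=spec)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, list[str]]:
    """Write phenotype CSV plus one tab-delimited ``.1D`` file per
    subject per atlas; returns a manifest of written paths."""
    if len(cohort.phenotypes) == 0:
        raise ValueError("refusing to write an empty cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pheno_path = out / "phenotypes.csv"
    cohort.phenotypes.to_csv(pheno_path, index=False)
    series_paths: list[str] = []
    for _, row in cohort.phenotypes.iterrows():
        sub = int(row["SUB_ID"])
        for name in cohort.atlas_names:
            key = (sub, name)
            if key not in cohort.timeseries:
                raise ValueError(f"missing time series for subject {sub}, {name}")
            path = out / f"{sub}_{name}.1D"
            np.savetxt(path, cohort.timeseries[key], fmt="%.12g", delimiter="\t")
            series_paths.append(str(path))
    return {"phenotypes": [str(pheno_path)], "timeseries": series_paths}
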