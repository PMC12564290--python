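"""Functional-connectivity views: Pearson FC matrices and upper-triangle
feature vectors, one view per atlas.

The strict upper triangle is vectorised in row-major order, i.e. pair
(i, j), i < j appears at position ``i*M - i*(i+1)//2 + (j - i - 1)``.  The
same ordering is assumed by the region-masking operators in
:mod:`popconn.explain`; it must never change independently there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import Cohort

__all__ = [
    "ConnectomeView",
    "pearson_fc",
    "upper_tri_vector",
    "vector_to_matrix",
    "build_views",
    "AtlasView",
]


@dataclass
class ConnectomeView:
    """One atlas view of one subject: FC matrix ``S`` and its strict
    upper-triangle vector ``U`` of length M(M-1)/2."""

    S: np.ndarray
    U: np.ndarray
    atlas: str
    subject: int


@dataclass
class AtlasView:
    """All subjects under one atlas: stacked node features ``X`` (N x d)
    and the per-subject FC matrices ``S_stack`` (N x M x M), in phenotype
    table order."""

    atlas: str
    X: np.ndarray
    S_stack: np.ndarray
    subjects: list[int]

    @property
    def n_rois(self) -> int:
        return self.S_stack.shape[1]


def pearson_fc(ts: np.ndarray, atlas: str = "", subject: int = -1) -> ConnectomeView:
    """Pearson correlation matrix of the columns of a T x M time-series.

    Zero-variance columns get correlation 0 against everything (keeping the
    feature dimension fixed); the diagonal is forced to 1.
    """
    ts = np.asarray(ts, dtype=np.float64)
    if ts.ndim != 2:
        raise ValueError(f"expected a 2-D time-series matrix, got ndim={ts.ndim}")
    t, m = ts.shape
    if t < 3:
        raise ValueError(f"need at least 3 timepoints for Pearson, got {t}")
    if m < 2:
        raise ValueError(f"need at least 2 ROIs, got {m}")
    if not np.all(np.isfinite(ts)):
        raise ValueError("time series contains non-finite values")
    centered = ts - ts.mean(axis=0)
    sd = centered.std(axis=0)
    ok = sd > 0
    safe_sd = np.where(ok, sd, 1.0)
    z = centered / safe_sd
    s = (z.T @ z) / t
    s = np.where(np.outer(ok, ok), s, 0.0)
    s = np.clip((s + s.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(s, 1.0)
    return ConnectomeView(S=s, U=upper_tri_vector(s), atlas=atlas, subject=subject)


def upper_tri_vector(s: np.ndarray) -> np.ndarray:
    """Row-major strict upper triangle of a square matrix."""
    s = np.asarray(s)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {s.shape}")
    i, j = np.triu_indices(s.shape[0], k=1)
    return s[i, j].copy()


def vector_to_matrix(u: np.ndarray, m: int, diag: float = 1.0) -> np.ndarray:
    """Inverse of :func:`upper_tri_vector` for symmetric matrices."""
    u = np.asarray(u)
    if u.shape != (m * (m - 1) // 2,):
        raise ValueError(f"length {u.size} inconsistent with M={m}")
    s = np.full((m, m), diag, dtype=np.float64)
    i, j = np.triu_indices(m, k=1)
    s[i, j] = u
    s[j, i] = u
    np.fill_diagonal(s, diag)
    return s


def build_views(cohort: Cohort) -> dict[str, AtlasView]:
    """Per-atlas stacked node features and FC matrices, rows ordered as in
    the phenotype table."""
    views: dict[str, AtlasView] = {}
    subjects = [int(s) for s in cohort.phenotypes["SUB_ID"]]
    for name in cohort.atlas_names:
        mats, feats = [], []
        for sub in subjects:
            key = (sub, name)
            if key not in cohort.timeseries:
                raise ValueError(f"missing time series for subject {sub}, atlas {name}")
            view = pearson_fc(cohort.timeseries[key], atlas=name, subject=sub)
            mats.append(view.S)
            feats.append(view.U)
        views[name] = AtlasView(
            atlas=name,
            X=np.stack(feats),
            S_stack=np.stack(mats),
            subjects=subjects,
        )
    return views
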