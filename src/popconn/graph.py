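"""Phenotype-scored population graph.

Subjects are nodes.  A raw score matrix ``A`` multiplies the imaging
similarity of two subjects' upper-triangle FC features by the number of
phenotype columns on which they agree (exact match for categorical columns,
|difference| < theta2 for quantitative ones).  Thresholding ``A`` at theta1
gives the binary edge mask ``F``; retained edges are weighted by the cosine
similarity of attention-enhanced phenotype embeddings, mapped to [0, 1].

Self-loops are deliberately absent from ``F`` and ``W``; the GCN adds them
once via its renormalised adjacency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import AtlasView
from .nn import glorot, rng_for

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationGraph",
    "phenotype_match",
    "imaging_similarity",
    "score_matrix",
    "binarize",
    "phenotype_embedding",
    "edge_weights",
    "build_population_graph",
    "column_kind",
]

#: Default phenotype columns used for graph edges (site + age).
DEFAULT_PHENOTYPES = ("SITE_ID", "AGE_AT_SCAN")

_KNOWN_KINDS = {
    "SITE_ID": "categorical",
    "SEX": "categorical",
    "EYE_STATUS_AT_SCAN": "categorical",
    "HANDEDNESS_CATEGORY": "categorical",
    "AGE_AT_SCAN": "quantitative",
    "FIQ": "quantitative",
}


def column_kind(table: pd.DataFrame, column: str) -> str:
    """categorical vs quantitative, by convention then dtype."""
    if column in _KNOWN_KINDS:
        return _KNOWN_KINDS[column]
    return "quantitative" if pd.api.types.is_float_dtype(table[column]) else "categorical"


@dataclass
class PopulationGraph:
    """Score matrix ``A``, edge mask ``F``, weighted adjacency ``W`` and the
    stacked node features ``X`` for one atlas."""

    atlas: str
    A: np.ndarray
    F: np.ndarray
    W: np.ndarray
    X: np.ndarray
    theta1: float
    theta2: float

    @property
    def n_subjects(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.F.sum()) // 2

    def edge_list(self) -> pd.DataFrame:
        i, j = np.triu_indices(self.n_subjects, k=1)
        return pd.DataFrame(
            {"i": i, "j": j, "A": self.A[i, j], "F": self.F[i, j], "W": self.W[i, j]}
        )

    def validate(self) -> None:
        for name, m in (("A", self.A), ("F", self.F), ("W", self.W)):
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError(f"{name} is not symmetric")
        if not np.isin(self.F, (0, 1)).all():
            raise ValueError("F must be binary")
        if np.any(self.W[self.F == 0] != 0):
            raise ValueError("W must vanish off the edge mask")
        if self.W.min() < 0 or self.W.max() > 1:
            raise ValueError("W entries must lie in [0, 1]")
        if np.any(np.diagonal(self.F)) or np.any(np.diagonal(self.W)):
            raise ValueError("F and W must have zero diagonals")


def phenotype_match(p_i, p_j, kind: str, theta2: float = 2.0) -> int:
    """Pairwise phenotype agreement indicator.

    Categorical columns match on equality; quantitative columns match when
    ``|p_i - p_j| < theta2`` (strict: a difference equal to theta2 does not
    match).
    """
    if kind == "categorical":
        return int(p_i == p_j)
    if kind == "quantitative":
        if theta2 <= 0:
            raise ValueError(f"theta2 must be > 0, got {theta2}")
        try:
            return int(abs(float(p_i) - float(p_j)) < theta2)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"quantitative comparison of non-numeric values {p_i!r}, {p_j!r}"
            ) from exc
    raise ValueError(f"unknown phenotype kind {kind!r}")


def imaging_similarity(u_i: np.ndarray, u_j: np.ndarray) -> float:
    """Cosine similarity of two feature vectors; 0 if either has zero norm."""
    u_i = np.asarray(u_i, dtype=np.float64)
    u_j = np.asarray(u_j, dtype=np.float64)
    if u_i.shape != u_j.shape:
        raise ValueError("feature vectors must have equal length")
    ni, nj = np.linalg.norm(u_i), np.linalg.norm(u_j)
    if ni == 0 or nj == 0:
        logger.warning("zero-norm feature vector in imaging similarity; returning 0")
        return 0.0
    return float(u_i @ u_j / (ni * nj))


def _cosine_matrix(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("%d zero-norm rows in cosine matrix; similarities set to 0",
                       int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    c = (x / safe[:, None]) @ (x / safe[:, None]).T
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    return np.clip(c, -1.0, 1.0)


def score_matrix(
    x: np.ndarray,
    table: pd.DataFrame,
    phenotypes: tuple[str, ...] = DEFAULT_PHENOTYPES,
    theta2: float = 2.0,
    similarity: str = "cosine",
) -> np.ndarray:
    """Edge score ``A[i, j] = sim(u_i, u_j) * sum_m match(P_im, P_jm)``.

    ``similarity`` may be "cosine" (default) or "pearson" (correlation of
    the feature vectors).
    """
    if len(phenotypes) == 0:
        raise ValueError("at least one phenotype column is required")
    missing = [c for c in phenotypes if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype columns missing from table: {missing}")
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    if len(table) != n:
        raise ValueError("feature matrix rows must align with phenotype rows")
    if similarity == "cosine":
        sim = _cosine_matrix(x)
    elif similarity == "pearson":
        sim = _cosine_matrix(x - x.mean(axis=1, keepdims=True))
    else:
        raise ValueError(f"unknown imaging similarity {similarity!r}")

    match_sum = np.zeros((n, n))
    for col in phenotypes:
        kind = column_kind(table, col)
        vals = table[col].to_numpy()
        if kind == "categorical":
            match_sum += (vals[:, None] == vals[None, :]).astype(float)
        else:
            if theta2 <= 0:
                raise ValueError(f"theta2 must be > 0, got {theta2}")
            v = vals.astype(np.float64)
            match_sum += (np.abs(v[:, None] - v[None, :]) < theta2).astype(float)
    a = sim * match_sum
    np.fill_diagonal(a, 0.0)
    return (a + a.T) / 2.0


def binarize(a: np.ndarray, theta1: float) -> np.ndarray:
    """Edge mask: 1 where the score reaches theta1 (inclusive), diagonal 0."""
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"score matrix must be square, got {a.shape}")
    f = (a >= theta1).astype(np.int8)
    np.fill_diagonal(f, 0)
    return f


def _encode_tokens(
    table: pd.DataFrame,
    phenotypes: tuple[str, ...],
    token_dim: int,
    seed: int,
) -> np.ndarray:
    """Encode each phenotype column as one token per subject.

    Categorical levels get fixed random embedding vectors; quantitative
    columns are z-scored over the cohort and scaled onto a fixed random
    direction.  Everything is keyed by ``seed`` and the column name.
    """
    n = len(table)
    tokens = np.zeros((n, len(phenotypes), token_dim))
    for m, col in enumerate(phenotypes):
        rng = rng_for(seed, "pheno-token", col)
        if column_kind(table, col) == "categorical":
            levels = sorted(map(str, pd.unique(table[col].astype(str))))
            emb = {lv: rng.standard_normal(token_dim) for lv in levels}
            tokens[:, m, :] = np.stack(
                [emb[str(v)] for v in table[col].astype(str)]
            )
        else:
            v = table[col].to_numpy(dtype=np.float64)
            sd = v.std()
            z = (v - v.mean()) / (sd if sd > 0 else 1.0)
            tokens[:, m, :] = z[:, None] * rng.standard_normal(token_dim)[None, :]
    return tokens


def phenotype_embedding(
    table: pd.DataFrame,
    phenotypes: tuple[str, ...] = DEFAULT_PHENOTYPES,
    token_dim: int = 8,
    seed: int = 0,
    return_attention: bool = False,
):
    """Attention-enhanced phenotype features, N x (Nm * token_dim).

    A single-head self-attention block with fixed (seeded, untrained)
    projections mixes the phenotype tokens of each subject; the enhanced
    tokens are flattened into one vector per subject.  Computed once — the
    population graph is static during training.
    """
    if token_dim < 1:
        raise ValueError(f"token_dim must be >= 1, got {token_dim}")
    if len(phenotypes) == 0:
        raise ValueError("at least one phenotype column is required")
    tokens = _encode_tokens(table, phenotypes, token_dim, seed)
    rng = rng_for(seed, "pheno-attn")
    wq = glorot(rng, token_dim, token_dim)
    wk = glorot(rng, token_dim, token_dim)
    wv = glorot(rng, token_dim, token_dim)
    q, k, v = tokens @ wq, tokens @ wk, tokens @ wv
    scores = q @ np.swapaxes(k, 1, 2) / np.sqrt(token_dim)
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    attn = e / e.sum(axis=-1, keepdims=True)
    enhanced = attn @ v + tokens  # residual keeps raw phenotype content
    embeddings = enhanced.reshape(len(table), -1)
    if return_attention:
        return embeddings, attn
    return embeddings


def edge_weights(embeddings: np.ndarray, f: np.ndarray) -> np.ndarray:
    """W[i, j] = (cos(E_i, E_j) + 1) / 2 on retained edges, else 0."""
    embeddings = np.asarray(embeddings, dtype=np.float64)
    if embeddings.shape[0] != f.shape[0]:
        raise ValueError("embedding rows must align with the edge mask")
    cos = _cosine_matrix(embeddings)
    w = (cos + 1.0) / 2.0
    w = np.where(f == 1, w, 0.0)
    np.fill_diagonal(w, 0.0)
    return (w + w.T) / 2.0


def build_population_graph(
    view: AtlasView,
    table: pd.DataFrame,
    theta1: float = 0.61,
    theta2: float = 2.0,
    phenotypes: tuple[str, ...] = DEFAULT_PHENOTYPES,
    token_dim: int = 8,
    seed: int = 0,
    similarity: str = "cosine",
) -> PopulationGraph:
    """Score -> threshold -> embed phenotypes -> weight edges, for one atlas."""
    a = score_matrix(view.X, table, phenotypes, theta2, similarity)
    f = binarize(a, theta1)
    emb = phenotype_embedding(table, phenotypes, token_dim, seed)
    w = edge_weights(emb, f)
    graph = PopulationGraph(
        atlas=view.atlas, A=a, F=f, W=w, X=view.X.copy(),
        theta1=theta1, theta2=theta2,
    )
    graph.validate()
    return graph
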