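"""Training objectives: multi-atlas consistency, cross-view contrastive
alignment, cross-entropy, and their weighted combination
L = L_ce + alpha * L_vc + beta * L_cl.

Conventions adopted here (documented in docs/methods.md):

* embeddings are L2-row-normalised before the consistency inner products,
  keeping the logistic sigmoid away from saturation regardless of
  embedding scale;
* the contrastive similarity is exp(cos(phi_i, phi_j) / tau) — the
  normalised-temperature form, with tau > 0 a smoothness parameter;
* the default positive mask is the identity: the same subject's local and
  global projections are the positive pair.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .nn import Linear, Module, rng_for

__all__ = [
    "ProjectionHead",
    "consistency_loss",
    "pairwise_similarity",
    "contrastive_loss",
    "cross_entropy",
    "total_loss",
    "positive_mask",
]

_EPS = 1e-12
_CLIP = 1e-7


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _row_normalize(x: Tensor) -> Tensor:
    norms = ((x * x).sum(axis=1, keepdims=True) + _EPS).sqrt()
    return x / norms


class ProjectionHead(Module):
    """Shared non-linear projection into the contrastive latent space:
    Linear -> ELU -> Linear, Xavier-initialised.  The same head (identical
    parameters) is applied to both the local and the global embeddings."""

    def __init__(self, in_dim: int, out_dim: int | None = None,
                 hidden: int | None = None, seed: int = 0):
        out_dim = out_dim or in_dim
        hidden = hidden or in_dim
        rng = rng_for(seed, "projection-head")
        self.lin1 = Linear(in_dim, hidden, rng)
        self.lin2 = Linear(hidden, out_dim, rng)

    def __call__(self, z) -> Tensor:
        return self.lin2(self.lin1(_as_tensor(z)).elu())


def consistency_loss(globals_per_view: list, locals_per_view: list) -> Tensor:
    """Cross-view agreement penalty.

    For every unordered pair of views (i, j), subjects' global embeddings
    G and local embeddings T (L2-row-normalised) should point the same
    way:  L_vc = -sum_{i<j} mean_n log sigma(<G_i,n, G_j,n> + <T_i,n, T_j,n>).
    A single view yields 0 (no pairs).
    """
    if len(globals_per_view) != len(locals_per_view):
        raise ValueError("need one global and one local embedding per view")
    n_views = len(globals_per_view)
    if n_views < 1:
        raise ValueError("at least one view is required")
    gs = [_row_normalize(_as_tensor(g)) for g in globals_per_view]
    ts = [_row_normalize(_as_tensor(t)) for t in locals_per_view]
    if n_views == 1:
        return Tensor(0.0)
    loss = None
    for i in range(n_views):
        for j in range(i + 1, n_views):
            inner = (gs[i] * gs[j]).sum(axis=1) + (ts[i] * ts[j]).sum(axis=1)
            term = -(inner.sigmoid().clip(_CLIP, 1.0).log()).mean()
            loss = term if loss is None else loss + term
    return loss


def pairwise_similarity(phi_a, phi_b, tau: float = 0.5) -> Tensor:
    """N x N matrix of exp(cosine(phi_a_i, phi_b_j) / tau)."""
    if tau <= 0:
        raise ValueError(f"temperature tau must be > 0, got {tau}")
    a, b = _as_tensor(phi_a), _as_tensor(phi_b)
    if np.any(np.linalg.norm(a.data, axis=1) == 0) or np.any(
        np.linalg.norm(b.data, axis=1) == 0
    ):
        raise ValueError("zero-norm projection row in similarity computation")

    def exact_norm(x: Tensor) -> Tensor:  # rows verified nonzero above
        return x / (x * x).sum(axis=1, keepdims=True).sqrt()

    cos = exact_norm(a) @ exact_norm(b).swapaxes(0, 1)
    return (cos * (1.0 / tau)).exp()


def positive_mask(n: int, kind: str = "diagonal",
                  labels: np.ndarray | None = None) -> np.ndarray:
    """Binary N x N positive-pair mask: "diagonal" (same subject) or
    "same_label" (supervised variant)."""
    if kind == "diagonal":
        return np.eye(n)
    if kind == "same_label":
        if labels is None:
            raise ValueError("same_label mask requires labels")
        labels = np.asarray(labels)
        return (labels[:, None] == labels[None, :]).astype(float)
    raise ValueError(f"unknown positive mask kind {kind!r}")


def contrastive_loss(phi_local, phi_global, mp: np.ndarray,
                     tau: float = 0.5, gamma: float = 0.4) -> Tensor:
    """Cross-view contrastive objective.

    L^lv = -mean_i log( sum_j sim(phi^lv_i, phi^gv_j) Mp_ij
                        / sum_j sim(phi^lv_i, phi^gv_j) ), and symmetrically
    for L^gv; the total is gamma * L^lv + (1 - gamma) * L^gv.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    mp = np.asarray(mp, dtype=np.float64)
    empty = np.flatnonzero(mp.sum(axis=1) == 0)
    if empty.size:
        raise ValueError(f"positive mask row {int(empty[0])} has no positives")

    def one_direction(a, b) -> Tensor:
        sim = pairwise_similarity(a, b, tau)
        ratio = (sim * Tensor(mp)).sum(axis=1) / sim.sum(axis=1)
        return -(ratio.clip(_CLIP, 1.0).log()).mean()

    l_lv = one_direction(phi_local, phi_global)
    l_gv = one_direction(phi_global, phi_local)
    return gamma * l_lv + (1.0 - gamma) * l_gv


def cross_entropy(y_hat, y: np.ndarray) -> Tensor:
    """Binary cross-entropy of positive-class probabilities against 0/1
    labels, with probabilities clipped to [1e-7, 1 - 1e-7]."""
    p = _as_tensor(y_hat)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"probability shape {p.shape} mismatches labels {y.shape}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    p = p.clip(_CLIP, 1.0 - _CLIP)
    return -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()).mean()


def total_loss(l_ce, l_vc, l_cl, alpha: float = 0.1, beta: float = 0.01) -> Tensor:
    """L = L_ce + alpha * L_vc + beta * L_cl."""
    return _as_tensor(l_ce) + alpha * _as_tensor(l_vc) + beta * _as_tensor(l_cl)
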