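"""Feature encoders.

Local branch — target-aware attention aggregator (TAA): a multi-head
self-attention block over ROI tokens followed by stacked node-centric
attention aggregation (NCAA) layers and a mean-pool readout.  Each ROI
token is that ROI's row of the subject's FC matrix (its connectivity
profile), so the token dimension equals the atlas size.

Global branch — a population GCN over the phenotype-weighted subject graph
with renormalised propagation D^-1/2 (W + I) D^-1/2, residual connections,
feature dropout and training-time DropEdge.  A Chebyshev polynomial
propagation variant is available behind ``variant="chebyshev"``.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, softmax
from .nn import Linear, Module, dropout, rng_for

__all__ = [
    "MultiHeadSelfAttention",
    "NCAALayer",
    "ncaa_update",
    "TargetAwareAggregator",
    "drop_edge",
    "normalized_adjacency",
    "GCNLayer",
    "PopulationGCN",
]


class MultiHeadSelfAttention(Module):
    """Standard MSA over the ROI (seq) axis; no positional encoding, so the
    block is permutation-equivariant in the seq axis."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads != 0:
            raise ValueError(f"token dim {dim} not divisible by n_heads {n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, seq, d = x.shape
        h, dh = self.n_heads, self.dim // self.n_heads

        def split(t: Tensor) -> Tensor:  # B x seq x D -> B x h x seq x dh
            return t.reshape(b, seq, h, dh).swapaxes(1, 2)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        attn = softmax(scores, axis=-1)
        out = (attn @ v).swapaxes(1, 2).reshape(b, seq, d)
        return self.wo(out)


class NCAALayer(Module):
    """Node-centric attention aggregation.

    For each center ROI i, a shared two-layer scorer is applied to the
    concatenation [h_i || h_j] for every other ROI j; softmax over j gives
    attention weights, and the update is h_i + sum_j alpha_ij h_j.  Because
    the scorer's first layer is linear in the concatenation, it is computed
    as separate center/neighbor projections summed pairwise — exactly
    equivalent, without materialising concatenated pairs.
    """

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.center = Linear(dim, hidden, rng)       # acts on h_i (carries bias)
        self.neighbor = Linear(dim, hidden, rng, bias=False)  # acts on h_j
        self.score = Linear(hidden, 1, rng)

    def attention(self, x: Tensor) -> Tensor:
        """B x seq x seq attention weights; the diagonal is exactly 0 and
        each row sums to 1 over the seq-1 neighbors."""
        b, seq, d = x.shape
        if seq < 2:
            raise ValueError("NCAA needs at least 2 ROIs")
        a = self.center(x).reshape(b, seq, 1, -1)
        c = self.neighbor(x).reshape(b, 1, seq, -1)
        pair = (a + c).tanh()
        scores = self.score(pair).reshape(b, seq, seq)
        mask = ~np.eye(seq, dtype=bool)[None, :, :]
        return softmax(scores, axis=-1, mask=mask)

    def __call__(self, x: Tensor) -> Tensor:
        return ncaa_update(x, self.attention(x))


def ncaa_update(x: Tensor, alpha: Tensor) -> Tensor:
    """h_i + sum_{j != i} alpha_ij h_j (alpha has a zero diagonal)."""
    if alpha.shape != (x.shape[0], x.shape[1], x.shape[1]):
        raise ValueError(f"attention shape {alpha.shape} mismatches tokens {x.shape}")
    return x + alpha @ x


class TargetAwareAggregator(Module):
    """MSA block, ``n_layers`` NCAA layers, mean-pool over ROIs, linear map
    to the embedding dimension.  Three attention layers are the default."""

    def __init__(self, n_rois: int, embed_dim: int = 32, n_layers: int = 3,
                 n_heads: int = 2, hidden: int = 32, seed: int = 0):
        if n_layers < 1:
            raise ValueError(f"n_layers must be >= 1, got {n_layers}")
        rng = rng_for(seed, "taa", n_rois)
        self.msa = MultiHeadSelfAttention(n_rois, n_heads, rng)
        self.ncaa_layers = [NCAALayer(n_rois, hidden, rng) for _ in range(n_layers)]
        self.readout = Linear(n_rois, embed_dim, rng)

    def __call__(self, s_stack) -> Tensor:
        x = s_stack if isinstance(s_stack, Tensor) else Tensor(np.asarray(s_stack))
        if x.ndim != 3:
            raise ValueError("expected N x M x M stacked FC matrices")
        x = self.msa(x)
        for layer in self.ncaa_layers:
            x = layer(x)
        return self.readout(x.mean(axis=1))


def drop_edge(w_adj: np.ndarray, rate: float, training: bool,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Remove each undirected edge independently with probability ``rate``
    during training; exact no-op at evaluation."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"edge-dropout rate must be in [0, 1), got {rate}")
    if not training or rate == 0.0:
        return w_adj
    if rng is None:
        raise ValueError("training-mode drop_edge requires an rng")
    w = np.asarray(w_adj, dtype=np.float64)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) >= rate
    out = np.zeros_like(w)
    kept_vals = w[iu, ju] * keep
    out[iu, ju] = kept_vals
    out[ju, iu] = kept_vals
    return out


def normalized_adjacency(w_adj: np.ndarray) -> np.ndarray:
    """D^-1/2 (W + I) D^-1/2 with D the degree matrix of W + I.

    Isolated nodes keep a unit self-loop, so degrees are always >= 1.
    """
    w = np.asarray(w_adj, dtype=np.float64)
    a_tilde = w + np.eye(w.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * np.outer(d_inv_sqrt, d_inv_sqrt)


class GCNLayer(Module):
    """ReLU(D^-1/2 (W+I) D^-1/2 H Theta) plus a residual connection
    (identity when dimensions match, a linear projection otherwise)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 residual: bool = True):
        self.theta = Linear(in_dim, out_dim, rng, bias=False)
        self.residual: Linear | str | None
        if not residual:
            self.residual = None
        elif in_dim == out_dim:
            self.residual = "identity"
        else:
            self.residual = Linear(in_dim, out_dim, rng, bias=False)

    def __call__(self, h: Tensor, norm_adj: np.ndarray) -> Tensor:
        out = (Tensor(norm_adj) @ self.theta(h)).relu()
        if self.residual == "identity":
            out = out + h
        elif isinstance(self.residual, Linear):
            out = out + self.residual(h)
        return out


class _ChebLayer(Module):
    """Chebyshev polynomial graph convolution of order K with residual."""

    def __init__(self, in_dim: int, out_dim: int, k: int,
                 rng: np.random.Generator):
        self.k = k
        self.thetas = [Linear(in_dim, out_dim, rng, bias=False) for _ in range(k)]
        self.residual = ("identity" if in_dim == out_dim
                         else Linear(in_dim, out_dim, rng, bias=False))

    def __call__(self, h: Tensor, scaled_lap: np.ndarray) -> Tensor:
        t_prev = h
        out = self.thetas[0](t_prev)
        if self.k > 1:
            t_curr = Tensor(scaled_lap) @ h
            out = out + self.thetas[1](t_curr)
            for k in range(2, self.k):
                t_next = Tensor(2.0 * scaled_lap) @ t_curr - t_prev
                t_prev, t_curr = t_curr, t_next
                out = out + self.thetas[k](t_curr)
        out = out.relu()
        if self.residual == "identity":
            out = out + h
        else:
            out = out + self.residual(h)
        return out


def _scaled_laplacian(w_adj: np.ndarray) -> np.ndarray:
    """2 L / lambda_max - I with lambda_max approximated by 2 (standard)."""
    w = np.asarray(w_adj, dtype=np.float64)
    deg = w.sum(axis=1)
    d_inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-12)), 0.0)
    return -(w * np.outer(d_inv_sqrt, d_inv_sqrt))


class PopulationGCN(Module):
    """Multi-layer GCN over the population graph: DropEdge (training only),
    then stacked convolution layers with feature dropout between them."""

    def __init__(self, in_dim: int, hidden: int = 32, out_dim: int = 32,
                 n_layers: int = 2, p_dropout: float = 0.2,
                 edge_dropout: float = 0.3, variant: str = "renorm",
                 cheb_k: int = 2, seed: int = 0):
        if n_layers < 1:
            raise ValueError(f"n_layers must be >= 1, got {n_layers}")
        if variant not in ("renorm", "chebyshev"):
            raise ValueError(f"unknown GCN variant {variant!r}")
        rng = rng_for(seed, "gcn", in_dim)
        dims = [in_dim] + [hidden] * (n_layers - 1) + [out_dim]
        if variant == "renorm":
            self.layers = [GCNLayer(dims[i], dims[i + 1], rng)
                           for i in range(n_layers)]
        else:
            self.layers = [_ChebLayer(dims[i], dims[i + 1], cheb_k, rng)
                           for i in range(n_layers)]
        self.variant = variant
        self.p_dropout = p_dropout
        self.edge_dropout = edge_dropout

    def __call__(self, x: np.ndarray, w_adj: np.ndarray, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        w = drop_edge(w_adj, self.edge_dropout, training, rng)
        prop = (normalized_adjacency(w) if self.variant == "renorm"
                else _scaled_laplacian(w))
        h = Tensor(np.asarray(x, dtype=np.float64))
        for i, layer in enumerate(self.layers):
            if i > 0:
                h = dropout(h, self.p_dropout, training, rng)
            h = layer(h, prop)
        return h
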