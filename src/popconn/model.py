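"""Full multi-view model: per-atlas local (TAA) and global (GCN) branches,
a shared projection head for contrastive alignment, and a fused linear
classifier over the concatenated branch embeddings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, softmax
from .config import TrainConfig
from .encoders import PopulationGCN, TargetAwareAggregator
from .graph import PopulationGraph
from .losses import ProjectionHead
from .nn import Linear, Module, rng_for

__all__ = ["MultiViewModel", "ModelOutput"]


@dataclass
class ModelOutput:
    """Per-view embeddings plus fused class probabilities."""

    globals_: dict[str, Tensor] = field(default_factory=dict)
    locals_: dict[str, Tensor] = field(default_factory=dict)
    phi_global: dict[str, Tensor] = field(default_factory=dict)
    phi_local: dict[str, Tensor] = field(default_factory=dict)
    probs: Tensor | None = None  # N x 2

    @property
    def p_positive(self) -> Tensor:
        return self.probs[:, 1]


class MultiViewModel(Module):
    """One TAA and one GCN per atlas (token/feature dims differ across
    atlases, so branches are not weight-shared), a single projection head
    shared by every branch, and a linear softmax classifier on the
    concatenation [G_v || T_v] over all views."""

    def __init__(self, atlas_dims: dict[str, tuple[int, int]],
                 config: TrainConfig, seed: int = 0):
        if not atlas_dims:
            raise ValueError("at least one atlas is required")
        config.validate()
        self.atlases = sorted(atlas_dims)
        self.config = config
        self.seed = seed
        k = config.embed_dim
        self.taa: dict[str, TargetAwareAggregator] = {}
        self.gcn: dict[str, PopulationGCN] = {}
        for idx, name in enumerate(self.atlases):
            n_rois, feat_dim = atlas_dims[name]
            if config.use_taa:
                self.taa[name] = TargetAwareAggregator(
                    n_rois, embed_dim=k, n_layers=config.taa.layers,
                    n_heads=config.taa.heads, hidden=config.taa.hidden,
                    seed=rng_for(seed, "taa-branch", idx).integers(2**31),
                )
            if config.use_gcn:
                self.gcn[name] = PopulationGCN(
                    feat_dim, hidden=config.gcn.hidden, out_dim=k,
                    n_layers=config.gcn.layers, p_dropout=config.gcn.dropout,
                    edge_dropout=config.gcn.edge_dropout,
                    variant=config.gcn.variant, cheb_k=config.gcn.cheb_k,
                    seed=rng_for(seed, "gcn-branch", idx).integers(2**31),
                )
        self.projection = ProjectionHead(
            k, config.proj_dim, seed=rng_for(seed, "proj").integers(2**31)
        )
        n_branches = int(config.use_taa) + int(config.use_gcn)
        self.classifier = Linear(
            len(self.atlases) * n_branches * k, 2,
            rng_for(seed, "classifier"),
        )

    def fuse_and_classify(self, embeddings: list[Tensor]) -> Tensor:
        """Concatenate branch embeddings and return softmax probabilities."""
        expected = (int(self.config.use_taa) + int(self.config.use_gcn)) \
            * len(self.atlases)
        if len(embeddings) != expected:
            raise ValueError(
                f"expected {expected} branch embeddings, got {len(embeddings)}"
            )
        logits = self.classifier(concat(embeddings, axis=1))
        return softmax(logits, axis=1)

    def forward(self, graphs: dict[str, PopulationGraph],
                s_stacks: dict[str, np.ndarray], training: bool = False,
                rng: np.random.Generator | None = None) -> ModelOutput:
        """One transductive pass over all subjects.

        ``graphs[name].X`` feeds the GCN branch; ``s_stacks[name]`` (N x M
        x M FC matrices) feeds the TAA branch.  At evaluation the pass is
        deterministic.
        """
        missing = [a for a in self.atlases if a not in graphs or a not in s_stacks]
        if missing:
            raise ValueError(f"missing inputs for atlases: {missing}")
        out = ModelOutput()
        fused: list[Tensor] = []
        for name in self.atlases:
            if self.config.use_gcn:
                g = self.gcn[name](graphs[name].X, graphs[name].W,
                                   training=training, rng=rng)
                out.globals_[name] = g
                out.phi_global[name] = self.projection(g)
                fused.append(g)
            if self.config.use_taa:
                t = self.taa[name](s_stacks[name])
                out.locals_[name] = t
                out.phi_local[name] = self.projection(t)
                fused.append(t)
        out.probs = self.fuse_and_classify(fused)
        return out
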