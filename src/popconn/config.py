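"""Run configuration: one nested, validated structure governing every
pipeline stage, serialisable to/from a single YAML or JSON file.

Defaults reproduce the recommended operating point: theta1 = 0.61,
theta2 = 2, alpha = 0.1, beta = 0.01, gamma = 0.4, learning rate 1e-4,
200 epochs, weight decay 5e-5, dropout 0.2, edge dropout 0.3, two hidden
GCN layers of width 32, three attention layers, 10-fold CV.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["GraphConfig", "TAAConfig", "GCNConfig", "LossConfig",
           "TrainConfig", "load_config", "save_config"]


@dataclass
class GraphConfig:
    theta1: float = 0.61
    theta2: float = 2.0
    phenotypes: tuple[str, ...] = ("SITE_ID", "AGE_AT_SCAN")
    token_dim: int = 8
    similarity: str = "cosine"

    def validate(self) -> None:
        if self.theta2 <= 0:
            raise ValueError(f"theta2 must be > 0, got {self.theta2}")
        if self.token_dim < 1:
            raise ValueError(f"token_dim must be >= 1, got {self.token_dim}")
        if self.similarity not in ("cosine", "pearson"):
            raise ValueError(f"unknown imaging similarity {self.similarity!r}")
        if len(self.phenotypes) == 0:
            raise ValueError("at least one phenotype column is required")


@dataclass
class TAAConfig:
    layers: int = 3
    heads: int = 2
    hidden: int = 16  # width of the shared pairwise attention scorer

    def validate(self) -> None:
        if self.layers < 1:
            raise ValueError(f"taa.layers must be >= 1, got {self.layers}")
        if self.heads < 1 or self.hidden < 1:
            raise ValueError("taa.heads and taa.hidden must be >= 1")


@dataclass
class GCNConfig:
    layers: int = 2
    hidden: int = 32
    dropout: float = 0.2
    edge_dropout: float = 0.3
    variant: str = "renorm"
    cheb_k: int = 2

    def validate(self) -> None:
        if self.layers < 1:
            raise ValueError(f"gcn.layers must be >= 1, got {self.layers}")
        for name in ("dropout", "edge_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"gcn.{name} must be in [0, 1), got {v}")
        if self.variant not in ("renorm", "chebyshev"):
            raise ValueError(f"gcn.variant must be renorm or chebyshev")


@dataclass
class LossConfig:
    alpha: float = 0.1
    beta: float = 0.01
    gamma: float = 0.4
    tau: float = 0.5
    positive_mask: str = "diagonal"

    def validate(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"loss.gamma must be in [0, 1], got {self.gamma}")
        if self.tau <= 0:
            raise ValueError(f"loss.tau must be > 0, got {self.tau}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss.alpha and loss.beta must be >= 0")
        if self.positive_mask not in ("diagonal", "same_label"):
            raise ValueError(
                f"loss.positive_mask must be diagonal or same_label")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 200
    weight_decay: float = 5e-5
    early_stop_start: int = 50
    patience: int = 30
    n_folds: int = 10
    seed: int = 0
    embed_dim: int = 32
    proj_dim: int = 32
    use_taa: bool = True
    use_gcn: bool = True
    use_gcl: bool = True
    graph: GraphConfig = field(default_factory=GraphConfig)
    taa: TAAConfig = field(default_factory=TAAConfig)
    gcn: GCNConfig = field(default_factory=GCNConfig)
    loss: LossConfig = field(default_factory=LossConfig)

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.patience < 1 or self.patience > self.epochs:
            raise ValueError("patience must be in [1, epochs]")
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if not (self.use_taa or self.use_gcn):
            raise ValueError("at least one of use_taa / use_gcn must be on")
        for sub in (self.graph, self.taa, self.gcn, self.loss):
            sub.validate()

    def desk_scale(self, epochs: int = 60, n_folds: int = 5) -> "TrainConfig":
        """Reduced-size copy for quick synthetic-cohort experiments.

        Fewer epochs and folds than the full-scale defaults, with the
        learning rate raised to 1e-3 so the small models converge within
        the shortened schedule.
        """
        cfg = _copy(self)
        cfg.epochs = epochs
        cfg.n_folds = n_folds
        cfg.learning_rate = 1e-3
        cfg.early_stop_start = min(self.early_stop_start, max(epochs // 2, 1))
        cfg.patience = min(self.patience, epochs)
        return cfg


def _copy(cfg: TrainConfig) -> TrainConfig:
    return _from_dict(TrainConfig, _to_dict(cfg))


def _to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _from_dict(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        if name in ("graph", "taa", "gcn", "loss") and isinstance(value, dict):
            sub_cls = {"graph": GraphConfig, "taa": TAAConfig,
                       "gcn": GCNConfig, "loss": LossConfig}[name]
            kwargs[name] = _from_dict(sub_cls, value)
        elif name == "phenotypes" or (isinstance(value, list)):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> TrainConfig:
    """Load and validate a YAML/JSON config; missing keys take defaults and
    unknown keys are rejected.  ``None`` or an empty file gives the pure
    defaults."""
    if path is None:
        cfg = TrainConfig()
        cfg.validate()
        return cfg
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else None
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    cfg = _from_dict(TrainConfig, data)
    cfg.validate()
    return cfg


def save_config(cfg: TrainConfig, path: str | Path) -> None:
    """Write the resolved configuration next to run outputs (provenance)."""
    path = Path(path)
    payload = _to_dict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
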