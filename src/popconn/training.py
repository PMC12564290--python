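"""Transductive training and stratified cross-validation.

Every forward pass sees the full population graph; only the loss masks
distinguish training from test subjects.  Cross-entropy is computed on the
training nodes (minus a small internal holdout used for early stopping);
the consistency and contrastive terms are likewise restricted to training
nodes so no information from test labels or test-node alignment leaks in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .autodiff import Tensor
from .config import TrainConfig
from .connectome import AtlasView, build_views
from .graph import PopulationGraph, build_population_graph
from .losses import (consistency_loss, contrastive_loss, cross_entropy,
                     positive_mask, total_loss)
from .model import ModelOutput, MultiViewModel
from .nn import Adam, rng_for
from .synthetic import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "DataBundle", "prepare_data", "compute_metrics", "auc_score",
    "stratified_folds", "train_fold", "cross_validate", "CVResult",
]

METRICS = ("ACC", "PRE", "RECALL", "F1", "AUC")


@dataclass
class DataBundle:
    """Everything the trainer needs: per-atlas views and population graphs,
    aligned with the phenotype table and labels."""

    views: dict[str, AtlasView]
    graphs: dict[str, PopulationGraph]
    labels: np.ndarray
    table: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.labels)

    @property
    def atlas_dims(self) -> dict[str, tuple[int, int]]:
        return {name: (v.n_rois, v.X.shape[1]) for name, v in self.views.items()}

    @property
    def s_stacks(self) -> dict[str, np.ndarray]:
        return {name: v.S_stack for name, v in self.views.items()}


def prepare_data(cohort: Cohort, config: TrainConfig) -> DataBundle:
    """FC views and one population graph per atlas."""
    views = build_views(cohort)
    graphs = {
        name: build_population_graph(
            view, cohort.phenotypes,
            theta1=config.graph.theta1, theta2=config.graph.theta2,
            phenotypes=config.graph.phenotypes,
            token_dim=config.graph.token_dim, seed=config.seed,
            similarity=config.graph.similarity,
        )
        for name, view in views.items()
    }
    labels = cohort.phenotypes["DX_GROUP"].to_numpy(dtype=int)
    return DataBundle(views=views, graphs=graphs, labels=labels,
                      table=cohort.phenotypes)


def auc_score(y_true: np.ndarray, y_prob: np.ndarray) -> float | None:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic;
    ``None`` when only one class is present."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        logger.warning("AUC undefined: only one class present")
        return None
    ranks = rankdata(y_prob)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def compute_metrics(y_true: np.ndarray, y_prob: np.ndarray,
                    threshold: float = 0.5) -> dict:
    """Confusion counts at ``threshold`` plus ACC/PRE/RECALL/F1/AUC.

    F1 is assembled from precision and recall; zero-denominator cases
    return 0 with a warning.
    """
    y_true = np.asarray(y_true).astype(int)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if y_true.shape != y_prob.shape:
        raise ValueError("y_true and y_prob must have equal length")
    if y_prob.min() < 0 or y_prob.max() > 1:
        raise ValueError("y_prob must lie in [0, 1]")
    y_pred = (y_prob >= threshold).astype(int)
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    acc = (tp + tn) / max(tp + tn + fp + fn, 1)
    if tp + fp == 0:
        logger.warning("no predicted positives; precision set to 0")
        pre = 0.0
    else:
        pre = tp / (tp + fp)
    if tp + fn == 0:
        logger.warning("no true positives in fold; recall set to 0")
        rec = 0.0
    else:
        rec = tp / (tp + fn)
    f1 = 0.0 if pre + rec == 0 else 2 * pre * rec / (pre + rec)
    return {"TP": tp, "TN": tn, "FP": fp, "FN": fn,
            "ACC": acc, "PRE": pre, "RECALL": rec, "F1": f1,
            "AUC": auc_score(y_true, y_prob)}


def stratified_folds(labels: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified partition into ``n_folds`` disjoint test sets."""
    labels = np.asarray(labels)
    if len(labels) < n_folds:
        raise ValueError("fewer subjects than folds")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"class with {counts.min()} subjects cannot stratify into "
            f"{n_folds} folds; use fewer folds"
        )
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


@dataclass
class FoldOutcome:
    model: MultiViewModel
    history: pd.DataFrame
    metrics: dict
    test_idx: np.ndarray
    y_prob: np.ndarray


@dataclass
class CVResult:
    folds: list[FoldOutcome]
    config: TrainConfig

    @property
    def fold_metrics(self) -> pd.DataFrame:
        return pd.DataFrame([f.metrics for f in self.folds])

    def aggregate(self) -> dict[str, dict[str, float]]:
        df = self.fold_metrics[list(METRICS)].astype(float)
        return {"mean": df.mean().to_dict(), "sd": df.std(ddof=1).to_dict()}

    @property
    def mean_acc(self) -> float:
        return float(self.fold_metrics["ACC"].mean())


def _loss_masks(train_idx: np.ndarray, seed: int, labels: np.ndarray):
    """Split the train mask into a fitting set and an early-stop holdout
    (~10%, at least 2 per class when possible)."""
    rng = rng_for(seed, "holdout")
    train_idx = np.asarray(train_idx)
    n_hold = max(int(round(0.1 * len(train_idx))), 2)
    if len(train_idx) - n_hold < 4:
        return train_idx, train_idx  # degenerate: monitor on train itself
    hold = []
    for cls in (0, 1):
        cls_idx = train_idx[labels[train_idx] == cls]
        take = max(int(round(n_hold * len(cls_idx) / len(train_idx))), 1)
        hold.extend(rng.permutation(cls_idx)[:take])
    hold = np.array(sorted(hold))
    fit = np.setdiff1d(train_idx, hold)
    return fit, hold


def train_fold(bundle: DataBundle, config: TrainConfig,
               train_idx: np.ndarray, test_idx: np.ndarray,
               seed: int | None = None) -> FoldOutcome:
    """Train one transductive fold and evaluate on its test mask."""
    config.validate()
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if train_idx.size == 0 or test_idx.size == 0:
        raise ValueError("train and test masks must be non-empty")
    seed = config.seed if seed is None else seed
    labels = bundle.labels
    fit_idx, hold_idx = _loss_masks(train_idx, seed, labels)

    model = MultiViewModel(bundle.atlas_dims, config, seed=seed)
    opt = Adam(model.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    mp_train = positive_mask(len(train_idx), config.loss.positive_mask,
                             labels[train_idx])
    use_gcl = (config.use_gcl and config.use_taa and config.use_gcn
               and config.loss.beta > 0)
    multi_view = (len(model.atlases) > 1 and config.use_gcl
                  and config.loss.alpha > 0)

    history = []
    best = {"loss": np.inf, "state": model.state(), "epoch": -1}
    since_best = 0
    for epoch in range(config.epochs):
        rng = rng_for(seed, "epoch", epoch)
        out = model.forward(bundle.graphs, bundle.s_stacks,
                            training=True, rng=rng)
        l_ce = cross_entropy(out.p_positive[fit_idx], labels[fit_idx])
        if multi_view:
            l_vc = consistency_loss(
                [out.globals_[a][train_idx] for a in model.atlases]
                if config.use_gcn else
                [out.locals_[a][train_idx] for a in model.atlases],
                [out.locals_[a][train_idx] for a in model.atlases]
                if config.use_taa else
                [out.globals_[a][train_idx] for a in model.atlases],
            )
        else:
            l_vc = Tensor(0.0)
        if use_gcl:
            terms = [
                contrastive_loss(out.phi_local[a][train_idx],
                                 out.phi_global[a][train_idx],
                                 mp_train, tau=config.loss.tau,
                                 gamma=config.loss.gamma)
                for a in model.atlases
            ]
            l_cl = terms[0]
            for t in terms[1:]:
                l_cl = l_cl + t
            l_cl = l_cl / len(terms)
        else:
            l_cl = Tensor(0.0)
        loss = total_loss(l_ce, l_vc, l_cl,
                          alpha=config.loss.alpha, beta=config.loss.beta)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        model.zero_grad()
        loss.backward()
        opt.step()

        eval_out = model.forward(bundle.graphs, bundle.s_stacks, training=False)
        val_loss = float(
            cross_entropy(eval_out.p_positive[hold_idx], labels[hold_idx]).data
        )
        history.append({
            "epoch": epoch, "loss": float(loss.data),
            "ce": float(l_ce.data), "vc": float(l_vc.data),
            "cl": float(l_cl.data), "val_ce": val_loss,
        })
        if val_loss < best["loss"] - 1e-9:
            best = {"loss": val_loss, "state": model.state(), "epoch": epoch}
            since_best = 0
        else:
            since_best += 1
        if epoch >= config.early_stop_start and since_best >= config.patience:
            logger.info("early stop at epoch %d (best %d)", epoch, best["epoch"])
            break

    model.load_state(best["state"])
    final = model.forward(bundle.graphs, bundle.s_stacks, training=False)
    y_prob = final.p_positive.data
    metrics = compute_metrics(labels[test_idx], y_prob[test_idx])
    return FoldOutcome(model=model, history=pd.DataFrame(history),
                       metrics=metrics, test_idx=test_idx,
                       y_prob=y_prob[test_idx])


def cross_validate(bundle: DataBundle, config: TrainConfig,
                   n_folds: int | None = None) -> CVResult:
    """Seeded stratified k-fold CV; every fold retrains from scratch."""
    config.validate()
    n_folds = n_folds or config.n_folds
    folds = stratified_folds(bundle.labels, n_folds, config.seed)
    all_idx = np.arange(bundle.n_subjects)
    outcomes = []
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        outcomes.append(
            train_fold(bundle, config, train_idx, test_idx,
                       seed=int(rng_for(config.seed, "fold", k).integers(2**31)))
        )
    return CVResult(folds=outcomes, config=config)
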