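"""Perturbation-driven region importance.

With a trained single-atlas model frozen, one ROI at a time is masked in
both model inputs — the FC matrix fed to the attention aggregator (row and
column zeroed) and the upper-triangle node features of the population
graph (the M-1 positions involving that ROI zeroed).  The drop in test
accuracy, Delta-Acc = Acc* - Acc~, is the region's importance index.

Graph edges and weights are kept fixed while node features are masked
(perturbing the inputs of a trained model, not rebuilding its graph);
``rebuild_graph=True`` recomputes A/F/W from the masked features instead.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .graph import PopulationGraph, build_population_graph
from .connectome import AtlasView
from .training import CVResult, DataBundle, compute_metrics

logger = logging.getLogger(__name__)

__all__ = ["mask_region_fc", "mask_region_ut", "region_importance",
           "rank_regions"]


def mask_region_fc(s: np.ndarray, i: int) -> np.ndarray:
    """Zero row i and column i (diagonal included) of an FC matrix.
    Works on a single M x M matrix or a stacked N x M x M array."""
    s = np.asarray(s)
    m = s.shape[-1]
    if not 0 <= i < m:
        raise ValueError(f"ROI index {i} out of range for M={m}")
    out = s.copy()
    out[..., i, :] = 0.0
    out[..., :, i] = 0.0
    return out


def _pair_positions(i: int, m: int) -> np.ndarray:
    """Positions in the row-major strict-upper-triangle vector whose pair
    contains ROI ``i`` (exactly M-1 of them)."""
    iu, ju = np.triu_indices(m, k=1)
    return np.flatnonzero((iu == i) | (ju == i))


def mask_region_ut(u: np.ndarray, i: int, m: int) -> np.ndarray:
    """Zero the M-1 upper-triangle feature positions involving ROI ``i``.
    Works on a single vector of length M(M-1)/2 or a stacked N x d array."""
    u = np.asarray(u)
    d = m * (m - 1) // 2
    if u.shape[-1] != d:
        raise ValueError(f"feature length {u.shape[-1]} inconsistent with M={m}")
    if not 0 <= i < m:
        raise ValueError(f"ROI index {i} out of range for M={m}")
    out = u.copy()
    out[..., _pair_positions(i, m)] = 0.0
    return out


def _masked_bundle_inputs(bundle: DataBundle, atlas: str, roi: int,
                          rebuild_graph: bool):
    view = bundle.views[atlas]
    m = view.n_rois
    s_masked = mask_region_fc(view.S_stack, roi)
    x_masked = mask_region_ut(view.X, roi, m)
    g = bundle.graphs[atlas]
    if rebuild_graph:
        masked_view = AtlasView(atlas=atlas, X=x_masked, S_stack=s_masked,
                                subjects=view.subjects)
        graph = build_population_graph(
            masked_view, bundle.table, theta1=g.theta1, theta2=g.theta2)
    else:
        graph = PopulationGraph(atlas=atlas, A=g.A, F=g.F, W=g.W,
                                X=x_masked, theta1=g.theta1, theta2=g.theta2)
    return {atlas: graph}, {atlas: s_masked}


def region_importance(cv: CVResult, bundle: DataBundle, atlas: str | None = None,
                      rebuild_graph: bool = False) -> pd.DataFrame:
    """Delta-Acc per ROI for a single-atlas cross-validated model.

    Acc* is the mean test-fold accuracy of the frozen per-fold models;
    Acc~ for each ROI re-evaluates those same models on masked inputs over
    the same test folds.
    """
    atlases = list(bundle.views)
    if len(atlases) != 1:
        raise ValueError(
            "region importance requires a single-atlas model; train in "
            "single-atlas mode first"
        )
    atlas = atlas or atlases[0]
    if atlas not in bundle.views:
        raise ValueError(f"unknown atlas {atlas!r}")
    m = bundle.views[atlas].n_rois
    labels = bundle.labels

    def mean_acc(graphs, stacks) -> float:
        accs = []
        for fold in cv.folds:
            out = fold.model.forward(graphs, stacks, training=False)
            p = out.p_positive.data[fold.test_idx]
            accs.append(compute_metrics(labels[fold.test_idx], p)["ACC"])
        return float(np.mean(accs))

    acc_star = mean_acc(bundle.graphs, bundle.s_stacks)
    rows = []
    for roi in range(m):
        graphs, stacks = _masked_bundle_inputs(bundle, atlas, roi, rebuild_graph)
        acc_tilde = mean_acc(graphs, stacks)
        rows.append({"roi": roi, "acc_masked": acc_tilde,
                     "delta_acc": acc_star - acc_tilde})
    table = pd.DataFrame(rows)
    table.attrs["baseline_acc"] = acc_star
    table.attrs["atlas"] = atlas
    return table


def rank_regions(table: pd.DataFrame, k: int = 10,
                 roi_labels: dict[int, str] | None = None) -> pd.DataFrame:
    """Top-k regions by descending Delta-Acc; ties broken by ROI index."""
    m = len(table)
    if k > m:
        logger.warning("k=%d exceeds ROI count %d; clipping", k, m)
        k = m
    ranked = table.sort_values(
        ["delta_acc", "roi"], ascending=[False, True], kind="mergesort"
    ).head(k).reset_index(drop=True)
    if roi_labels:
        ranked = ranked.assign(
            label=[roi_labels.get(int(r), "") for r in ranked["roi"]]
        )
    ranked.attrs.update(table.attrs)
    return ranked
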