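"""Map trained-model evidence back to connectivity space.

Two complementary importance analyses:

* **Reconstruction edge importance** exploits exact invertibility: pre-FC
  output units are scored by the class contrast of their FC weights, only the
  top fraction is kept (the rest zeroed), and the masked output is pushed back
  through the inverse block stack. The magnitude of the reconstructed input at
  each (ROI, selected-feature) slot measures how much of the class-relevant
  output lives on that input feature; slot scores are scattered to
  connectivity edges through the screening map.

* **Lesion node importance** removes one ROI at a time — its feature row is
  zeroed, feature slots sourced from it are zeroed, and the node is isolated
  in both graphs (Laplacians rebuilt) — then the cross-validated models are
  retrained and the accuracy drop relative to baseline is the node's score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import Cohort
from .graphs import SparseGraph
from .invertible import stack_forward, stack_inverse
from .model import (
    CVResult,
    IDGCNParams,
    PreparedCohort,
    TrainConfig,
    bases_from_graph,
    cross_validate,
    evaluate,
    features_for,
    model_forward,
    prepare_cohort,
    train,
)
from .screening import FeatureSelection

__all__ = [
    "ImportanceReport",
    "reconstruction_edge_importance",
    "lesion_node_importance",
]


@dataclass
class ImportanceReport:
    """Edge-importance ranking and/or per-node lesion scores."""

    edge_scores: np.ndarray | None = None  # symmetric N x N, zero diagonal
    top_edges: list[tuple[int, int, float]] = field(default_factory=list)
    node_scores: np.ndarray | None = None  # accuracy drop per ROI
    top_fraction: float = 0.10
    roi_ids: list[str] = field(default_factory=list)


def reconstruction_edge_importance(
    params: IDGCNParams,
    spatial_basis: np.ndarray,
    functional_basis: np.ndarray,
    selection: FeatureSelection,
    samples: np.ndarray,
    top_fraction: float = 0.10,
    roi_ids: list[str] | None = None,
) -> ImportanceReport:
    """Edge importance by masked inverse reconstruction.

    ``samples`` is a (B, N, F) stack of screened feature matrices with
    matching (B, K, N, N) bases. Output units (the 2*N*F flattened pre-FC
    features, site covariates excluded) are ranked by |w_1 - w_0| of their FC
    weight rows; the top ``top_fraction`` are retained, the rest zeroed, and
    the masked outputs are inverted back to input space. Mean absolute
    reconstructed magnitude per (ROI, slot) is scattered to edges via the
    screening selection and symmetrised by max.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 2:
        samples = samples[None]
        spatial_basis = np.asarray(spatial_basis)[None]
        functional_basis = np.asarray(functional_basis)[None]
    if samples.shape[0] < 1:
        raise ValueError("need at least one sample")
    n, f = samples.shape[1], samples.shape[2]
    nf2 = 2 * n * f
    unit_w = params.fc_weights[:nf2]
    unit_score = np.abs(unit_w[:, 1] - unit_w[:, 0])
    if np.all(unit_score == 0):
        raise ValueError("no discriminative weights: FC layer looks untrained")

    n_keep = math.ceil(top_fraction * nf2)
    order = np.argsort(-unit_score, kind="stable")
    keep = np.zeros(nf2, dtype=bool)
    keep[order[:n_keep]] = True
    mask1 = keep[: n * f].reshape(n, f)
    mask2 = keep[n * f :].reshape(n, f)

    z1, z2 = stack_forward(samples, params.blocks, spatial_basis, functional_basis)
    x1r, x2r = stack_inverse(
        z1 * mask1, z2 * mask2, params.blocks, spatial_basis, functional_basis
    )
    slot_scores = 0.5 * (np.abs(x1r) + np.abs(x2r)).mean(axis=0)  # (N, F)

    edge_scores = np.zeros((selection.n_rois, selection.n_rois))
    for r in range(selection.n_rois):
        cols = np.concatenate([selection.static_indices[r], selection.dynamic_indices[r]])
        for slot, j in enumerate(cols):
            s = slot_scores[r, slot]
            if s > edge_scores[r, j]:
                edge_scores[r, j] = s
    edge_scores = np.maximum(edge_scores, edge_scores.T)

    iu, ju = np.triu_indices(selection.n_rois, k=1)
    scored = edge_scores[iu, ju] > 0
    n_edges = int(scored.sum())
    n_top = math.ceil(top_fraction * n_edges) if n_edges else 0
    vals = edge_scores[iu, ju]
    rank = np.lexsort((ju, iu, -vals))
    top_edges = [
        (int(iu[r]), int(ju[r]), float(vals[r])) for r in rank[:n_top] if vals[r] > 0
    ]
    return ImportanceReport(
        edge_scores=edge_scores,
        top_edges=top_edges,
        top_fraction=top_fraction,
        roi_ids=roi_ids or list(selection.roi_ids),
    )


def _lesion_graph(g: SparseGraph, r: int) -> SparseGraph:
    adj = g.adjacency.copy()
    adj[r, :] = 0.0
    adj[:, r] = 0.0
    return SparseGraph(adjacency=adj, kind=g.kind, k=g.k)


def _lesion_features(
    X: np.ndarray, sel: FeatureSelection, r: int
) -> np.ndarray:
    """Zero ROI r's feature row and every slot whose source ROI is r."""
    X = X.copy()
    X[:, r, :] = 0.0
    for row in range(sel.n_rois):
        cols = np.concatenate([sel.static_indices[row], sel.dynamic_indices[row]])
        hit = np.flatnonzero(cols == r)
        if hit.size:
            X[:, row, hit] = 0.0
    return X


def lesion_node_importance(
    cohort: Cohort,
    config: TrainConfig | None = None,
    M: int = 8,
    J: int = 4,
    k: int = 3,
    K: int = 3,
    folds: int = 5,
    seed: int = 0,
    window_length: int = 30,
    stride: int = 10,
    rf_trees: int = 500,
    use_dynamic: bool = True,
    baseline: CVResult | None = None,
    prep: PreparedCohort | None = None,
) -> ImportanceReport:
    """Accuracy drop from excluding each ROI, under retrained per-fold models.

    The baseline is the ordinary cross-validation; each lesion reuses the
    baseline fold splits and screening selections, masks the lesioned node
    out of features and graphs, and retrains the fold models.
    """
    if cohort.n_rois <= 2:
        raise ValueError("lesion analysis needs more than 2 ROIs")
    if config is None:
        config = TrainConfig()
    if not use_dynamic:
        J = 0
    if prep is None:
        prep = prepare_cohort(
            cohort, k=k, K=K, window_length=window_length, stride=stride,
            use_dynamic=use_dynamic,
        )
    if baseline is None:
        baseline = cross_validate(
            cohort, config, M=M, J=J, k=k, K=K, folds=folds, seed=seed,
            window_length=window_length, stride=stride, rf_trees=rf_trees,
            use_dynamic=use_dynamic, prep=prep,
        )
    base_acc = baseline.mean["accuracy"]
    labels = prep.labels
    node_scores = np.zeros(cohort.n_rois)
    for r in range(cohort.n_rois):
        sp_basis = np.stack(
            [bases_from_graph(_lesion_graph(g, r), K) for g in prep.spatial_graphs]
        )
        fn_basis = np.stack(
            [bases_from_graph(_lesion_graph(g, r), K) for g in prep.functional_graphs]
        )
        accs = []
        for fold_no, fold in enumerate(baseline.folds):
            tr, te = fold.train_idx, fold.test_idx
            sel = fold.selection
            X_tr = _lesion_features(features_for(prep, sel, tr), sel, r)
            X_te = _lesion_features(features_for(prep, sel, te), sel, r)
            fold_cfg = replace(config, seed=config.seed + fold_no)
            params, _ = train(
                {
                    "features": X_tr,
                    "spatial_basis": sp_basis[tr],
                    "functional_basis": fn_basis[tr],
                    "sites": prep.sites_onehot[tr],
                    "labels": labels[tr],
                },
                fold_cfg,
                K=K,
            )
            probs = model_forward(
                X_te, sp_basis[te], fn_basis[te], params, prep.sites_onehot[te]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                accs.append(evaluate(probs[:, 1], labels[te]).accuracy)
        node_scores[r] = base_acc - float(np.mean(accs))
    return ImportanceReport(node_scores=node_scores, roi_ids=list(cohort.roi_ids))
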