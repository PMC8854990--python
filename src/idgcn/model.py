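"""ID-GCN assembly, training and cross-validated evaluation.

The classifier stacks three invertible blocks (spatial-GCN phi, functional-GCN
omega per block) over the screened N x (M+J) feature matrix, flattens both
output lanes, appends a one-hot acquisition-site covariate, and applies a
fully connected layer with softmax. Training minimises mean cross-entropy
with Adam; everything runs in numpy with analytic gradients (verified against
central differences in the test suite).

Evaluation follows the standard confusion-count definitions
(accuracy = (TP+TN)/n, precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R)) plus rank-based AUC, under stratified k-fold cross-validation
with the supervised screening refit inside each training fold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .cohort import Cohort
from .connectivity import (
    ConnectivityMatrix,
    DynamicFeatureMatrix,
    dynamic_variation_features,
    pearson_correlation_matrix,
    sliding_window_correlations,
)
from .gcn_core import ChebGCNLayerParams, chebyshev_basis
from .graphs import (
    SparseGraph,
    knn_functional_graph,
    knn_spatial_graph,
    normalized_laplacian,
    scaled_laplacian,
)
from .invertible import (
    IDGCNBlocks,
    InvertibleBlockParams,
    stack_backward,
    stack_forward,
    stack_forward_cached,
)
from .screening import FeatureSelection, apply_screening, fit_screening

__all__ = [
    "IDGCNParams",
    "TrainConfig",
    "Metrics",
    "model_forward",
    "cross_entropy",
    "init_params",
    "train",
    "evaluate",
    "cross_validate",
    "CVResult",
]


@dataclass
class IDGCNParams:
    """All trainable weights: block stack plus the final FC layer."""

    blocks: IDGCNBlocks
    fc_weights: np.ndarray  # (2*N*F + n_sites, 2)
    fc_bias: np.ndarray  # (2,)
    n_rois: int
    n_sites: int

    def __post_init__(self) -> None:
        self.fc_weights = np.asarray(self.fc_weights, dtype=float)
        self.fc_bias = np.asarray(self.fc_bias, dtype=float)
        want = 2 * self.n_rois * self.blocks.n_features + self.n_sites
        if self.fc_weights.shape != (want, 2):
            raise ValueError(
                f"fc_weights must be {want} x 2, got {self.fc_weights.shape}"
            )
        if self.fc_bias.shape != (2,):
            raise ValueError("fc_bias must have length 2")

    @property
    def n_features(self) -> int:
        return self.blocks.n_features


@dataclass
class TrainConfig:
    """First-order training hyperparameters (full batch by default)."""

    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int | None = None
    optimizer: str = "adam"
    weight_decay: float = 0.0
    seed: int = 0
    n_blocks: int = 3
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs and learning_rate must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be positive")


@dataclass
class Metrics:
    """Confusion counts and the derived classification metrics."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float  # nan when labels are single-class

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def init_params(
    n_rois: int,
    n_features: int,
    n_sites: int,
    K: int = 3,
    n_blocks: int = 3,
    seed: int = 0,
    init_scale: float = 0.1,
) -> IDGCNParams:
    """Seeded random initialisation (small weights keep the additive stack stable)."""
    rng = np.random.default_rng(seed)
    scale = init_scale / math.sqrt(max(K * n_features, 1))
    blocks = []
    for _ in range(n_blocks):
        blocks.append(
            InvertibleBlockParams(
                phi=ChebGCNLayerParams(
                    rng.normal(0.0, scale, size=(K, n_features, n_features))
                ),
                omega=ChebGCNLayerParams(
                    rng.normal(0.0, scale, size=(K, n_features, n_features))
                ),
            )
        )
    d = 2 * n_rois * n_features + n_sites
    fc_w = rng.normal(0.0, 0.01, size=(d, 2))
    return IDGCNParams(
        blocks=IDGCNBlocks(blocks),
        fc_weights=fc_w,
        fc_bias=np.zeros(2),
        n_rois=n_rois,
        n_sites=n_sites,
    )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _fc_input(z1: np.ndarray, z2: np.ndarray, sites: np.ndarray) -> np.ndarray:
    b = z1.shape[0]
    return np.concatenate([z1.reshape(b, -1), z2.reshape(b, -1), sites], axis=1)


def model_forward(
    features: np.ndarray,
    spatial_basis: np.ndarray,
    functional_basis: np.ndarray,
    params: IDGCNParams,
    site: np.ndarray,
) -> np.ndarray:
    """Class-probability pair(s) for one subject (N x F) or a batch (B x N x F)."""
    features = np.asarray(features, dtype=float)
    single = features.ndim == 2
    if single:
        features = features[None]
        spatial_basis = np.asarray(spatial_basis)[None]
        functional_basis = np.asarray(functional_basis)[None]
        site = np.asarray(site, dtype=float)[None]
    site = np.asarray(site, dtype=float)
    if site.shape[-1] != params.n_sites:
        raise ValueError(
            f"site one-hot has width {site.shape[-1]}, model expects {params.n_sites}"
        )
    z1, z2 = stack_forward(features, params.blocks, spatial_basis, functional_basis)
    logits = _fc_input(z1, z2, site) @ params.fc_weights + params.fc_bias
    probs = _softmax(logits)
    return probs[0] if single else probs


def cross_entropy(y: float, y_hat: float, eps: float = 1e-12) -> float:
    """Binary cross-entropy of one prediction, -y log p - (1-y) log(1-p)."""
    p = min(max(float(y_hat), eps), 1.0 - eps)
    y = float(y)
    return -y * math.log(p) - (1.0 - y) * math.log(1.0 - p)


def _loss_and_grads(
    X: np.ndarray,
    Tsp: np.ndarray,
    Tfn: np.ndarray,
    sites: np.ndarray,
    labels: np.ndarray,
    params: IDGCNParams,
) -> tuple[float, dict]:
    """Mean cross-entropy over the batch plus gradients for every weight."""
    b = X.shape[0]
    z1, z2, caches = stack_forward_cached(X, params.blocks, Tsp, Tfn)
    h = _fc_input(z1, z2, sites)
    logits = h @ params.fc_weights + params.fc_bias
    probs = _softmax(logits)
    p1 = np.clip(probs[:, 1], 1e-12, 1 - 1e-12)
    loss = float(
        np.mean(-labels * np.log(p1) - (1 - labels) * np.log(1 - p1))
    )
    onehot = np.zeros_like(probs)
    onehot[np.arange(b), labels] = 1.0
    dlogits = (probs - onehot) / b
    dW_fc = h.T @ dlogits
    db_fc = dlogits.sum(axis=0)
    dh = dlogits @ params.fc_weights.T
    nf = params.n_rois * params.n_features
    dz1 = dh[:, :nf].reshape(z1.shape)
    dz2 = dh[:, nf : 2 * nf].reshape(z2.shape)
    _, block_grads = stack_backward(dz1, dz2, params.blocks, caches, Tsp, Tfn)
    return loss, {"fc_weights": dW_fc, "fc_bias": db_fc, "blocks": block_grads}


def _flatten_params(params: IDGCNParams) -> list[np.ndarray]:
    arrs = []
    for blk in params.blocks.blocks:
        arrs.extend([blk.phi.weights, blk.omega.weights])
    arrs.extend([params.fc_weights, params.fc_bias])
    return arrs


def _flatten_grads(grads: dict, n_blocks: int) -> list[np.ndarray]:
    arrs = []
    for g in grads["blocks"]:
        arrs.extend([g["phi"], g["omega"]])
    arrs.extend([grads["fc_weights"], grads["fc_bias"]])
    return arrs


def train(
    dataset: dict,
    config: TrainConfig,
    params: IDGCNParams | None = None,
    K: int = 3,
) -> tuple[IDGCNParams, list[float]]:
    """Fit the model by Adam (or plain SGD) on a prepared dataset.

    ``dataset`` holds ``features`` (B, N, F), ``spatial_basis`` and
    ``functional_basis`` (B, K, N, N), ``sites`` (B, n_sites one-hot) and
    ``labels`` (B,). Returns the fitted parameters and the per-epoch loss
    trace; raises on divergence (non-finite loss).
    """
    X = np.asarray(dataset["features"], dtype=float)
    Tsp = np.asarray(dataset["spatial_basis"], dtype=float)
    Tfn = np.asarray(dataset["functional_basis"], dtype=float)
    sites = np.asarray(dataset["sites"], dtype=float)
    labels = np.asarray(dataset["labels"], dtype=int)
    b, n, f = X.shape
    if np.unique(labels).size < 2:
        raise ValueError("training requires both classes")
    if params is None:
        params = init_params(
            n, f, sites.shape[1], K=K, n_blocks=config.n_blocks,
            seed=config.seed, init_scale=config.init_scale,
        )

    arrs = _flatten_params(params)
    m = [np.zeros_like(a) for a in arrs]
    v = [np.zeros_like(a) for a in arrs]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    rng = np.random.default_rng(config.seed)
    losses: list[float] = []

    for epoch in range(config.epochs):
        if config.batch_size is None or config.batch_size >= b:
            batches = [np.arange(b)]
        else:
            perm = rng.permutation(b)
            batches = [
                perm[i : i + config.batch_size] for i in range(0, b, config.batch_size)
            ]
        epoch_loss = 0.0
        for idx in batches:
            loss, grads = _loss_and_grads(
                X[idx], Tsp[idx], Tfn[idx], sites[idx], labels[idx], params
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={loss})"
                )
            epoch_loss += loss * len(idx)
            garrs = _flatten_grads(grads, config.n_blocks)
            step += 1
            for a, g, mi, vi in zip(arrs, garrs, m, v):
                if config.weight_decay:
                    # decoupled decay (AdamW-style): not fed through the
                    # adaptive moments, where L2 loses its effect
                    a *= 1.0 - config.learning_rate * config.weight_decay
                if config.optimizer == "adam":
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    mhat = mi / (1 - beta1**step)
                    vhat = vi / (1 - beta2**step)
                    a -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
                else:
                    a -= config.learning_rate * g
        losses.append(epoch_loss / b)
    return params, losses


def evaluate(predictions: np.ndarray, labels: np.ndarray) -> Metrics:
    """Confusion-count metrics plus rank-based AUC at decision threshold 0.5.

    ``predictions`` are class-1 probabilities. AUC is the normalized
    Mann-Whitney statistic of the class-1 scores; with single-class labels it
    is undefined and reported as nan with a warning.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must align")
    pred = (p >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n = len(y)
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    n1 = int(y.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        warnings.warn("AUC undefined for single-class labels", RuntimeWarning)
        auc = float("nan")
    else:
        ranks = rankdata(p)
        auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1)
    return Metrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=accuracy, precision=precision, recall=recall, f1=f1, auc=float(auc),
    )


# ---------------------------------------------------------------------------
# cohort-level preparation and cross-validation
# ---------------------------------------------------------------------------


@dataclass
class PreparedCohort:
    """Connectivity features and graph bases computed once per cohort."""

    static: list[ConnectivityMatrix]
    dynamic: list[DynamicFeatureMatrix] | None
    functional_graphs: list[SparseGraph]
    spatial_graphs: list[SparseGraph]
    functional_basis: np.ndarray  # (S, K, N, N)
    spatial_basis: np.ndarray
    sites_onehot: np.ndarray  # (S, n_sites)
    labels: np.ndarray


def bases_from_graph(g: SparseGraph, K: int) -> np.ndarray:
    lap = scaled_laplacian(normalized_laplacian(g))
    return chebyshev_basis(lap.L_tilde, K)


def prepare_cohort(
    cohort: Cohort,
    k: int = 3,
    K: int = 3,
    window_length: int = 30,
    stride: int = 10,
    use_dynamic: bool = True,
    use_spatial: bool = True,
) -> PreparedCohort:
    """Compute per-subject connectivity features, graphs and Chebyshev bases.

    These steps are unsupervised, so computing them once for the whole cohort
    leaks nothing across CV folds. When ``use_spatial`` is off, phi shares the
    functional graph (spatial-information ablation).
    """
    if cohort.timeseries is not None:
        static = [pearson_correlation_matrix(ts) for ts in cohort.timeseries]
        dynamic = None
        if use_dynamic:
            dynamic = [
                dynamic_variation_features(
                    sliding_window_correlations(ts, window_length, stride),
                    window_length,
                    stride,
                )
                for ts in cohort.timeseries
            ]
    else:
        if use_dynamic:
            raise ValueError(
                "dynamic features require time series; this cohort has only "
                "precomputed connectivity (set use_dynamic=False)"
            )
        static = list(cohort.connectivity)
        dynamic = None

    functional = [knn_functional_graph(c, k) for c in static]
    if use_spatial:
        spatial = [knn_spatial_graph(cohort.coords, c, k) for c in static]
    else:
        spatial = functional
    fn_basis = np.stack([bases_from_graph(g, K) for g in functional])
    sp_basis = (
        fn_basis if not use_spatial else np.stack([bases_from_graph(g, K) for g in spatial])
    )
    n_sites = cohort.n_sites
    onehot = np.zeros((cohort.n_subjects, n_sites))
    onehot[np.arange(cohort.n_subjects), cohort.sites] = 1.0
    return PreparedCohort(
        static=static,
        dynamic=dynamic,
        functional_graphs=functional,
        spatial_graphs=spatial,
        functional_basis=fn_basis,
        spatial_basis=sp_basis,
        sites_onehot=onehot,
        labels=np.asarray(cohort.labels, dtype=int),
    )


def features_for(
    prep: PreparedCohort, sel: FeatureSelection, indices: np.ndarray
) -> np.ndarray:
    """Stack screened feature matrices for the given subject indices."""
    return np.stack(
        [
            apply_screening(
                prep.static[i],
                prep.dynamic[i] if prep.dynamic is not None else None,
                sel,
            ).values
            for i in indices
        ]
    )


@dataclass
class FoldResult:
    metrics: Metrics
    params: IDGCNParams
    selection: FeatureSelection
    train_idx: np.ndarray
    test_idx: np.ndarray
    probabilities: np.ndarray


@dataclass
class CVResult:
    """Per-fold metrics plus their mean and SD for each headline metric."""

    folds: list[FoldResult]
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = ("accuracy", "auc", "precision", "recall", "f1")
        vals = {m: np.array([getattr(f.metrics, m) for f in self.folds]) for m in names}
        self.mean = {m: float(np.nanmean(v)) for m, v in vals.items()}
        self.sd = {m: float(np.nanstd(v)) for m, v in vals.items()}


def cross_validate(
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
    use_spatial: bool = True,
    prep: PreparedCohort | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the full pipeline.

    Screening is refit inside every fold on that fold's training subjects
    only; folds are stratified by diagnosis and seeded. A precomputed
    ``prep`` (unsupervised features/bases) may be passed to avoid
    recomputation across repeated runs on the same cohort.
    """
    if cohort.n_subjects < folds:
        raise ValueError(f"{cohort.n_subjects} subjects cannot fill {folds} folds")
    if config is None:
        config = TrainConfig()
    if not use_dynamic:
        J = 0
    if prep is None:
        prep = prepare_cohort(
            cohort, k=k, K=K, window_length=window_length, stride=stride,
            use_dynamic=use_dynamic, use_spatial=use_spatial,
        )
    labels = prep.labels
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    results: list[FoldResult] = []
    for fold_no, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        sel = fit_screening(
            [prep.static[i] for i in tr],
            [prep.dynamic[i] for i in tr] if prep.dynamic is not None else None,
            labels[tr],
            M=M,
            J=J,
            seed=seed + fold_no,
            n_estimators=rf_trees,
        )
        X_tr = features_for(prep, sel, tr)
        X_te = features_for(prep, sel, te)
        fold_cfg = replace(config, seed=config.seed + fold_no)
        params, _ = train(
            {
                "features": X_tr,
                "spatial_basis": prep.spatial_basis[tr],
                "functional_basis": prep.functional_basis[tr],
                "sites": prep.sites_onehot[tr],
                "labels": labels[tr],
            },
            fold_cfg,
            K=K,
        )
        probs = model_forward(
            X_te, prep.spatial_basis[te], prep.functional_basis[te], params,
            prep.sites_onehot[te],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            metrics = evaluate(probs[:, 1], labels[te])
        results.append(
            FoldResult(
                metrics=metrics, params=params, selection=sel,
                train_idx=tr, test_idx=te, probabilities=probs[:, 1],
            )
        )
    return CVResult(folds=results)
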