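"""Random-forest pre-screening of connectivity features.

With N ROIs each node carries N-1 static correlation features and N-1
dynamic-variability features — most of them noise for any one disorder. The
feature space is reduced per ROI, not by dropping ROIs: for every ROI one
random-forest classifier is fit on that ROI's static feature row (subjects x
(N-1) off-diagonal columns) against the diagnosis labels, and the M columns
with the largest impurity importance are kept; the same procedure applied to
the dynamic rows keeps J columns. The model input is then the N x (M+J)
matrix of selected static and dynamic features per ROI.

Screening is supervised, so it must be refit inside every cross-validation
fold on that fold's training subjects only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .connectivity import ConnectivityMatrix, DynamicFeatureMatrix

__all__ = ["FeatureSelection", "SubjectFeatures", "fit_screening", "apply_screening"]


@dataclass
class FeatureSelection:
    """Per-ROI selected feature columns (indices are source-ROI indices)."""

    static_indices: list[np.ndarray]  # per ROI, length M
    dynamic_indices: list[np.ndarray]  # per ROI, length J
    M: int
    J: int
    fit_seed: int
    roi_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.static_indices = [np.asarray(ix, dtype=int) for ix in self.static_indices]
        self.dynamic_indices = [np.asarray(ix, dtype=int) for ix in self.dynamic_indices]
        n = len(self.static_indices)
        if len(self.dynamic_indices) != n:
            raise ValueError("static and dynamic selections must cover the same ROIs")
        for r, (s, d) in enumerate(zip(self.static_indices, self.dynamic_indices)):
            for name, ix, want in (("static", s, self.M), ("dynamic", d, self.J)):
                if len(ix) != want:
                    raise ValueError(f"ROI {r}: {name} selection has {len(ix)} != {want}")
                if len(np.unique(ix)) != len(ix):
                    raise ValueError(f"ROI {r}: duplicate {name} selection")
                if np.any(ix == r):
                    raise ValueError(f"ROI {r}: self-index selected")

    @property
    def n_rois(self) -> int:
        return len(self.static_indices)


@dataclass
class SubjectFeatures:
    """N x (M+J) screened feature matrix for one subject."""

    values: np.ndarray
    selection: FeatureSelection

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        sel = self.selection
        if self.values.shape != (sel.n_rois, sel.M + sel.J):
            raise ValueError(
                f"feature matrix must be {sel.n_rois} x {sel.M + sel.J}, "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("screened features must be finite")


def _top_columns(
    rows: np.ndarray,
    labels: np.ndarray,
    candidates: np.ndarray,
    m: int,
    seed: int,
    n_estimators: int,
) -> np.ndarray:
    """Fit one forest on the candidate columns; return the top-m by importance.

    Ties are broken by lower (original) column index.
    """
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(rows, labels)
    imp = forest.feature_importances_
    order = np.lexsort((candidates, -imp))
    chosen = candidates[order[:m]]
    return np.sort(chosen)


def fit_screening(
    train_static: Sequence[ConnectivityMatrix],
    train_dynamic: Sequence[DynamicFeatureMatrix] | None,
    labels: Sequence[int],
    M: int,
    J: int,
    seed: int = 0,
    n_estimators: int = 500,
) -> FeatureSelection:
    """Fit the per-ROI forests on training subjects and keep the top-M / top-J columns.

    ``train_dynamic`` may be None when J = 0 (static-only ablation). Must only
    ever see training-fold subjects.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("screening needs both classes in the training labels")
    if len(train_static) != len(labels):
        raise ValueError("one static matrix required per training label")
    n = train_static[0].n_rois
    if not 0 <= M <= n - 1:
        raise ValueError(f"M must be in [0, {n - 1}], got {M}")
    if not 0 <= J <= n - 1:
        raise ValueError(f"J must be in [0, {n - 1}], got {J}")
    if J > 0 and train_dynamic is None:
        raise ValueError("J > 0 requires dynamic feature matrices")

    static_stack = np.stack([c.values for c in train_static])  # (S, N, N)
    dyn_stack = (
        np.stack([d.values for d in train_dynamic]) if train_dynamic is not None else None
    )
    ss = np.random.SeedSequence(seed)
    static_sel: list[np.ndarray] = []
    dynamic_sel: list[np.ndarray] = []
    for r in range(n):
        candidates = np.delete(np.arange(n), r)
        seed_s, seed_d = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
        if M > 0:
            static_sel.append(
                _top_columns(
                    static_stack[:, r, candidates], labels, candidates, M, seed_s, n_estimators
                )
            )
        else:
            static_sel.append(np.empty(0, dtype=int))
        if J > 0:
            dynamic_sel.append(
                _top_columns(
                    dyn_stack[:, r, candidates], labels, candidates, J, seed_d, n_estimators
                )
            )
        else:
            dynamic_sel.append(np.empty(0, dtype=int))
    return FeatureSelection(
        static_indices=static_sel,
        dynamic_indices=dynamic_sel,
        M=M,
        J=J,
        fit_seed=seed,
        roi_ids=list(train_static[0].roi_ids),
    )


def apply_screening(
    subject_static: ConnectivityMatrix,
    subject_dynamic: DynamicFeatureMatrix | None,
    sel: FeatureSelection,
) -> SubjectFeatures:
    """Assemble one subject's N x (M+J) screened feature matrix."""
    if sel.roi_ids and subject_static.roi_ids != sel.roi_ids:
        raise ValueError(
            "subject ROI ids do not match the atlas the selection was fit on"
        )
    if subject_static.n_rois != sel.n_rois:
        raise ValueError(
            f"subject has {subject_static.n_rois} ROIs, selection expects {sel.n_rois}"
        )
    if sel.J > 0 and subject_dynamic is None:
        raise ValueError("selection includes dynamic features but none were given")
    rows = []
    for r in range(sel.n_rois):
        parts = [subject_static.values[r, sel.static_indices[r]]]
        if sel.J > 0:
            parts.append(subject_dynamic.values[r, sel.dynamic_indices[r]])
        rows.append(np.concatenate(parts) if parts else np.empty(0))
    return SubjectFeatures(values=np.vstack(rows), selection=sel)
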