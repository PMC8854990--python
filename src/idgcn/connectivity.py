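"""Static and dynamic functional-connectivity features from ROI time series.

A subject's static feature matrix is the N x N Pearson correlation matrix of
its ROI time series; each row is that node's feature vector. Dynamic features
summarise nonstationarity: correlations are recomputed in sliding windows and
the per-edge variability (population standard deviation across windows) forms
an auxiliary N x N feature matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "DynamicFeatureMatrix",
    "pearson_correlation_matrix",
    "sliding_window_correlations",
    "dynamic_variation_features",
]


def _default_roi_ids(n: int) -> list[str]:
    return [f"roi{i}" for i in range(n)]


@dataclass
class TimeSeriesMatrix:
    """T x N matrix of ROI signals (rows = time points, columns = ROIs)."""

    values: np.ndarray
    roi_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (time x ROI) matrix")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 time points")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite entries")
        if not self.roi_ids:
            self.roi_ids = _default_roi_ids(self.values.shape[1])
        if len(self.roi_ids) != self.values.shape[1]:
            raise ValueError("roi_ids length does not match column count")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N correlation matrix; row i is node i's feature vector.

    Diagonal entries are 1, except for zero-variance ROIs whose whole
    row/column (including the diagonal) is zeroed so matrix shapes stay
    stable across subjects.
    """

    values: np.ndarray
    roi_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.abs(self.values).max(initial=0.0) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")
        if not self.roi_ids:
            self.roi_ids = _default_roi_ids(n)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class DynamicFeatureMatrix:
    """Per-edge temporal standard deviation of windowed correlations."""

    values: np.ndarray
    window_length: int = 0
    stride: int = 0
    roi_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("dynamic feature matrix must be square")
        if (self.values < -1e-12).any():
            raise ValueError("temporal variations must be non-negative")
        if not self.roi_ids:
            self.roi_ids = _default_roi_ids(n)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def _corrcoef_safe(block: np.ndarray, roi_ids: list[str]) -> np.ndarray:
    """Pearson correlations with zero-variance columns zeroed (with warning)."""
    sd = block.std(axis=0)
    dead = sd == 0.0
    if dead.any():
        names = [roi_ids[i] for i in np.flatnonzero(dead)]
        warnings.warn(
            f"zero-variance ROI(s) {names}: correlation row/column set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(block, rowvar=False)
    r = np.atleast_2d(r)
    r[~np.isfinite(r)] = 0.0
    r[dead, :] = 0.0
    r[:, dead] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, np.where(dead, 0.0, 1.0))
    return r


def pearson_correlation_matrix(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Full-length Pearson correlation matrix of the ROI time series.

    Zero-variance ROIs yield an all-zero row/column and a ``RuntimeWarning``
    rather than an error, keeping shapes consistent across subjects.
    """
    return ConnectivityMatrix(_corrcoef_safe(ts.values, ts.roi_ids), list(ts.roi_ids))


def sliding_window_correlations(
    ts: TimeSeriesMatrix, window_length: int, stride: int
) -> list[ConnectivityMatrix]:
    """Correlation matrix in each sliding window.

    Window t covers rows ``[t*stride, t*stride + window_length)``; the number
    of windows is ``floor((T - window_length)/stride) + 1``.
    """
    T = ts.n_timepoints
    if window_length < 2:
        raise ValueError(f"window_length must be >= 2, got {window_length}")
    if window_length > T:
        raise ValueError(
            f"window_length {window_length} exceeds series length {T}"
        )
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    n_win = (T - window_length) // stride + 1
    out = []
    for t in range(n_win):
        block = ts.values[t * stride : t * stride + window_length]
        out.append(ConnectivityMatrix(_corrcoef_safe(block, ts.roi_ids), list(ts.roi_ids)))
    return out


def dynamic_variation_features(
    windows: Sequence[ConnectivityMatrix],
    window_length: int = 0,
    stride: int = 0,
) -> DynamicFeatureMatrix:
    """Population SD of each edge's correlation across windows (diagonal 0).

    Requires at least two windows; with a single window the temporal
    variation is undefined.
    """
    if len(windows) < 2:
        raise ValueError(
            f"need at least 2 windows to measure temporal variation, got {len(windows)}"
        )
    stack = np.stack([w.values for w in windows])
    sd = stack.std(axis=0)  # population (divide-by-n) SD
    np.fill_diagonal(sd, 0.0)
    return DynamicFeatureMatrix(
        sd, window_length=window_length, stride=stride, roi_ids=list(windows[0].roi_ids)
    )
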