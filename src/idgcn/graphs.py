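"""k-nearest graphs over ROIs and their (rescaled) normalized Laplacians.

Two graphs are built per subject. The *functional* graph keeps, for each
node, the k neighbours with the largest absolute correlation; the *spatial*
graph's skeleton keeps the k nearest neighbours by centroid Euclidean
distance, and retained edges are weighted by the absolute correlation. Both
are symmetrised by union, so every node has at least k neighbours.

Edge weights are |r| rather than signed correlation: the normalized Laplacian
L = I - D^{-1/2} A D^{-1/2} needs non-negative degrees, and taking magnitudes
keeps strong anti-correlations in the graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.linalg

from .connectivity import ConnectivityMatrix

__all__ = [
    "SparseGraph",
    "ScaledLaplacian",
    "knn_functional_graph",
    "knn_spatial_graph",
    "normalized_laplacian",
    "scaled_laplacian",
]


@dataclass
class SparseGraph:
    """Symmetric non-negative weighted adjacency with zero diagonal."""

    adjacency: np.ndarray
    kind: Literal["functional", "spatial"]
    k: int

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if (a < 0).any():
            raise ValueError("adjacency weights must be non-negative")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.abs(np.diag(a)).max(initial=0.0) != 0.0:
            raise ValueError("adjacency diagonal must be zero (no self-loops)")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class ScaledLaplacian:
    """Normalized Laplacian L, its rescaled form L~, and lambda_max of L.

    L~ = (2/lambda_max) L - I maps the spectrum of L from [0, lambda_max]
    into [-1, 1], the domain on which Chebyshev polynomials are defined.
    """

    L: np.ndarray
    L_tilde: np.ndarray | None = None
    lambda_max: float | None = None


def _check_k(k: int, n: int) -> None:
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}] for {n} nodes, got {k}")


def _knn_mask(score: np.ndarray, k: int, largest: bool) -> np.ndarray:
    """Per-row top-k mask (self excluded), ties broken by lower column index."""
    n = score.shape[0]
    key = -score if largest else score
    mask = np.zeros((n, n), dtype=bool)
    cols = np.arange(n)
    for i in range(n):
        order = np.lexsort((cols, key[i]))
        order = order[order != i]
        mask[i, order[:k]] = True
    return mask


def knn_functional_graph(X: ConnectivityMatrix, k: int) -> SparseGraph:
    """k-nearest graph keeping each node's strongest |correlation| neighbours.

    Symmetrised by union: an edge is kept if either endpoint selected it, so
    nodes end up with between k and N-1 neighbours. Weight is |r|.
    """
    _check_k(k, X.n_rois)
    w = np.abs(X.values).astype(float)
    np.fill_diagonal(w, 0.0)
    mask = _knn_mask(w, k, largest=True)
    keep = mask | mask.T
    adj = np.where(keep, w, 0.0)
    return SparseGraph(adjacency=adj, kind="functional", k=k)


def knn_spatial_graph(coords: np.ndarray, X: ConnectivityMatrix, k: int) -> SparseGraph:
    """k-nearest graph on centroid distance, weighted by |correlation|.

    The skeleton depends only on geometry (per-node k smallest Euclidean
    distances, union-symmetrised); subject-specific correlations then weight
    the retained edges. Duplicate coordinates are allowed (distance 0 sorts
    first).
    """
    coords = np.asarray(coords, dtype=float)
    n = X.n_rois
    if coords.shape != (n, 3):
        raise ValueError(f"coords must be {n} x 3")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")
    _check_k(k, n)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    mask = _knn_mask(d, k, largest=False)
    keep = mask | mask.T
    w = np.abs(X.values).astype(float)
    np.fill_diagonal(w, 0.0)
    adj = np.where(keep, w, 0.0)
    return SparseGraph(adjacency=adj, kind="spatial", k=k)


def normalized_laplacian(g: SparseGraph) -> ScaledLaplacian:
    """L = I - D^{-1/2} A D^{-1/2} with weighted degrees D.

    Isolated nodes (degree 0) use the convention D^{-1/2} = 0, which leaves
    L_ii = 1 on their diagonal.
    """
    a = g.adjacency
    deg = a.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    L = np.eye(g.n_nodes) - (dinv_sqrt[:, None] * a * dinv_sqrt[None, :])
    L = 0.5 * (L + L.T)
    return ScaledLaplacian(L=L)


def scaled_laplacian(lap: ScaledLaplacian) -> ScaledLaplacian:
    """Fill in L~ = (2/lambda_max) L - I using the exact largest eigenvalue.

    A degenerate edgeless graph (L = I exactly) takes the conventional
    lambda_max := 2, which makes L~ the zero operator.
    """
    n = lap.L.shape[0]
    if np.array_equal(lap.L, np.eye(n)):
        lam = 2.0
    else:
        evals = scipy.linalg.eigvalsh(lap.L)
        lam = float(evals[-1])
        if lam <= 1e-12:
            lam = 2.0
    L_tilde = (2.0 / lam) * lap.L - np.eye(lap.L.shape[0])
    return ScaledLaplacian(L=lap.L, L_tilde=L_tilde, lambda_max=lam)
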