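"""Chebyshev-polynomial spectral graph convolution.

A graph convolution filters node features in the spectral domain of the
normalized Laplacian, X_out = sigma(U g(Lambda) U^T X). Expanding the filter
g in Chebyshev polynomials of the rescaled Laplacian L~ avoids the explicit
eigendecomposition: with T_0 = I, T_1 = L~, T_k = 2 L~ T_{k-1} - T_{k-2},
the layer computes

    X_out = sigma( sum_{k=0}^{K-1} T_k(L~) X W_k )

with one trainable F_in x F_out weight matrix per polynomial order (ChebNet
form). The eigendecomposition route is kept as ``spectral_oracle_forward``
for cross-checking the polynomial implementation.

Forward/backward passes operate on either a single subject (basis (K, N, N),
features (N, F)) or a batch (leading subject axis on both); weights are
always shared across the batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "ChebGCNLayerParams",
    "chebyshev_basis",
    "gcn_layer_forward",
    "spectral_oracle_forward",
]


@dataclass
class ChebGCNLayerParams:
    """Per-order Chebyshev weight stack W_k plus the layer activation."""

    weights: np.ndarray  # (K, F_in, F_out)
    activation: Literal["identity", "relu"] = "relu"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3:
            raise ValueError("weights must be a (K, F_in, F_out) stack")
        if self.weights.shape[0] < 1:
            raise ValueError("need at least one Chebyshev order (K >= 1)")
        if self.activation not in ("identity", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def K(self) -> int:
        return self.weights.shape[0]


def chebyshev_basis(L_tilde: np.ndarray, K: int) -> np.ndarray:
    """Stack [T_0(L~), ..., T_{K-1}(L~)] via the three-term recurrence."""
    L_tilde = np.asarray(L_tilde, dtype=float)
    n = L_tilde.shape[0]
    if L_tilde.shape != (n, n):
        raise ValueError("L_tilde must be square")
    if K < 1:
        raise ValueError("K must be >= 1")
    T = np.empty((K, n, n))
    T[0] = np.eye(n)
    if K > 1:
        T[1] = L_tilde
    for k in range(2, K):
        T[k] = 2.0 * L_tilde @ T[k - 1] - T[k - 2]
    return T


def _apply_activation(S: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(S, 0.0)
    return S


def cheb_conv(basis: np.ndarray, X: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Pre-activation sum_k T_k X W_k; batched when inputs carry a subject axis."""
    if X.ndim == 2:
        return np.einsum("knm,mf,kfg->ng", basis, X, weights, optimize=True)
    return np.einsum("bknm,bmf,kfg->bng", basis, X, weights, optimize=True)


def cheb_conv_backward(
    basis: np.ndarray, X: np.ndarray, weights: np.ndarray, dS: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients (dX, dW) of the pre-activation sum_k T_k X W_k."""
    if X.ndim == 2:
        dW = np.einsum("knm,mf,ng->kfg", basis, X, dS, optimize=True)
        dX = np.einsum("knm,ng,kfg->mf", basis, dS, weights, optimize=True)
    else:
        dW = np.einsum("bknm,bmf,bng->kfg", basis, X, dS, optimize=True)
        dX = np.einsum("bknm,bng,kfg->bmf", basis, dS, weights, optimize=True)
    return dX, dW


def gcn_layer_forward(
    X_in: np.ndarray, basis: np.ndarray | Sequence[np.ndarray], params: ChebGCNLayerParams
) -> np.ndarray:
    """One Chebyshev graph-convolution layer, X_out = sigma(sum_k T_k X W_k)."""
    basis = np.asarray(basis, dtype=float)
    X_in = np.asarray(X_in, dtype=float)
    K = params.K
    k_found = basis.shape[1] if basis.ndim == 4 else basis.shape[0]
    if k_found != K:
        raise ValueError(f"basis has {k_found} orders, params expect {K}")
    f_in = params.weights.shape[1]
    if X_in.shape[-1] != f_in:
        raise ValueError(
            f"feature dimension mismatch: X has {X_in.shape[-1]}, weights expect {f_in}"
        )
    if X_in.shape[-2] != basis.shape[-1]:
        raise ValueError(
            f"node dimension mismatch: X has {X_in.shape[-2]} rows, "
            f"basis is {basis.shape[-1]} x {basis.shape[-1]}"
        )
    S = cheb_conv(basis, X_in, params.weights)
    return _apply_activation(S, params.activation)


def gcn_layer_forward_cached(
    X_in: np.ndarray, basis: np.ndarray, params: ChebGCNLayerParams
) -> tuple[np.ndarray, dict]:
    """Forward pass keeping what the backward pass needs."""
    S = cheb_conv(basis, X_in, params.weights)
    out = _apply_activation(S, params.activation)
    return out, {"X": X_in, "S": S}


def gcn_layer_backward(
    dOut: np.ndarray, cache: dict, basis: np.ndarray, params: ChebGCNLayerParams
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients (dX_in, dW) given the gradient at the layer output."""
    if params.activation == "relu":
        dS = dOut * (cache["S"] > 0)
    else:
        dS = dOut
    return cheb_conv_backward(basis, cache["X"], params.weights, dS)


def spectral_oracle_forward(
    X_in: np.ndarray, L: np.ndarray, coefficients: Sequence[float], K: int | None = None
) -> np.ndarray:
    """Eigendecomposition route: U (sum_k beta_k T_k(Lambda~)) U^T X.

    Scalar filter coefficients beta_k are applied eigenvalue-wise to the
    rescaled spectrum Lambda~ = (2/lambda_max) Lambda - I. Used as the
    independent oracle for the polynomial layer (identity activation).
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if K is None:
        K = len(coefficients)
    if len(coefficients) != K:
        raise ValueError("need one coefficient per polynomial order")
    evals, U = scipy.linalg.eigh(np.asarray(L, dtype=float))
    lam_max = float(evals[-1])
    if lam_max <= 1e-12:
        lam_max = 2.0
    lam_tilde = (2.0 / lam_max) * evals - 1.0
    # Chebyshev recurrence on the eigenvalue vector
    tk_prev = np.ones_like(lam_tilde)
    tk = lam_tilde.copy()
    filt = coefficients[0] * tk_prev
    if K > 1:
        filt = filt + coefficients[1] * tk
    for k in range(2, K):
        tk_prev, tk = tk, 2.0 * lam_tilde * tk - tk_prev
        filt = filt + coefficients[k] * tk
    return U @ (filt[:, None] * (U.T @ np.asarray(X_in, dtype=float)))
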