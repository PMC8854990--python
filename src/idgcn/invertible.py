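"""Additive invertible blocks coupling a spatial and a functional GCN.

Each block takes two same-shape feature maps (x1, x2) and computes

    y1 = x1 + phi(x2)        phi: Chebyshev GCN on the spatial graph
    y2 = x2 + omega(y1)      omega: Chebyshev GCN on the functional graph
    z1 = 0.5 (y1 + y2)
    z2 = 0.5 (y2 - y1)

which is exactly invertible for *any* functions phi and omega:

    y1 = z1 - z2, y2 = z1 + z2, x2 = y2 - omega(y1), x1 = y1 - phi(x2).

A stack of such blocks (three by default) therefore lets the input features
be reconstructed exactly from the pre-classifier output — the property the
whole interpretability pipeline rests on. The first block receives the same
feature matrix on both lanes; each later block consumes the (z1, z2) of its
predecessor. Reconstruction paths run in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .gcn_core import (
    ChebGCNLayerParams,
    gcn_layer_backward,
    gcn_layer_forward,
    gcn_layer_forward_cached,
)

__all__ = [
    "InvertibleBlockParams",
    "IDGCNBlocks",
    "block_forward",
    "block_inverse",
    "stack_forward",
    "stack_inverse",
]


@dataclass
class InvertibleBlockParams:
    """phi (spatial-graph GCN) and omega (functional-graph GCN) of one block."""

    phi: ChebGCNLayerParams
    omega: ChebGCNLayerParams

    def __post_init__(self) -> None:
        for name, p in (("phi", self.phi), ("omega", self.omega)):
            if p.weights.shape[1] != p.weights.shape[2]:
                raise ValueError(
                    f"{name} must preserve the feature dimension "
                    f"(got {p.weights.shape[1]} -> {p.weights.shape[2]})"
                )
        if self.phi.weights.shape[1] != self.omega.weights.shape[1]:
            raise ValueError("phi and omega must share the feature dimension")


@dataclass
class IDGCNBlocks:
    """Ordered stack of invertible blocks (three by default)."""

    blocks: list[InvertibleBlockParams]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("need at least one block")
        dims = {b.phi.weights.shape[1] for b in self.blocks}
        if len(dims) != 1:
            raise ValueError("all blocks must share the feature dimension")

    @property
    def n_features(self) -> int:
        return self.blocks[0].phi.weights.shape[1]


def _coupling_forward(
    x1: np.ndarray, x2: np.ndarray, phi: Callable, omega: Callable
) -> tuple[np.ndarray, np.ndarray]:
    """Additive coupling + mixing for arbitrary callables phi, omega."""
    y1 = x1 + phi(x2)
    y2 = x2 + omega(y1)
    return 0.5 * (y1 + y2), 0.5 * (y2 - y1)


def _coupling_inverse(
    z1: np.ndarray, z2: np.ndarray, phi: Callable, omega: Callable
) -> tuple[np.ndarray, np.ndarray]:
    """Exact algebraic inverse of :func:`_coupling_forward`."""
    y1 = z1 - z2
    y2 = z1 + z2
    x2 = y2 - omega(y1)
    x1 = y1 - phi(x2)
    return x1, x2


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"lane shapes differ: {a.shape} vs {b.shape}")
    return a, b


def block_forward(
    x1: np.ndarray,
    x2: np.ndarray,
    params: InvertibleBlockParams,
    spatial_basis: np.ndarray,
    functional_basis: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass of one invertible block: (x1, x2) -> (z1, z2)."""
    x1, x2 = _check_pair(x1, x2)
    return _coupling_forward(
        x1,
        x2,
        lambda v: gcn_layer_forward(v, spatial_basis, params.phi),
        lambda v: gcn_layer_forward(v, functional_basis, params.omega),
    )


def block_inverse(
    z1: np.ndarray,
    z2: np.ndarray,
    params: InvertibleBlockParams,
    spatial_basis: np.ndarray,
    functional_basis: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact inverse of :func:`block_forward` with the same parameters."""
    z1, z2 = _check_pair(z1, z2)
    return _coupling_inverse(
        z1,
        z2,
        lambda v: gcn_layer_forward(v, spatial_basis, params.phi),
        lambda v: gcn_layer_forward(v, functional_basis, params.omega),
    )


def stack_forward(
    x: np.ndarray,
    blocks: IDGCNBlocks,
    spatial_basis: np.ndarray,
    functional_basis: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the block stack; the first block receives (x, x)."""
    z1 = z2 = np.asarray(x, dtype=float)
    for b in blocks.blocks:
        z1, z2 = block_forward(z1, z2, b, spatial_basis, functional_basis)
    return z1, z2


def stack_inverse(
    z1: np.ndarray,
    z2: np.ndarray,
    blocks: IDGCNBlocks,
    spatial_basis: np.ndarray,
    functional_basis: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the block stack in reverse order; returns the first block's input pair."""
    for b in reversed(blocks.blocks):
        z1, z2 = block_inverse(z1, z2, b, spatial_basis, functional_basis)
    return z1, z2


# ---------------------------------------------------------------------------
# training support: cached forward + backprop through the stack
# ---------------------------------------------------------------------------


def stack_forward_cached(
    x: np.ndarray,
    blocks: IDGCNBlocks,
    spatial_basis: np.ndarray,
    functional_basis: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    z1 = z2 = np.asarray(x, dtype=float)
    caches: list[dict] = []
    for b in blocks.blocks:
        phi_out, phi_cache = gcn_layer_forward_cached(z2, spatial_basis, b.phi)
        y1 = z1 + phi_out
        om_out, om_cache = gcn_layer_forward_cached(y1, functional_basis, b.omega)
        y2 = z2 + om_out
        caches.append({"phi": phi_cache, "omega": om_cache})
        z1, z2 = 0.5 * (y1 + y2), 0.5 * (y2 - y1)
    return z1, z2, caches


def stack_backward(
    dz1: np.ndarray,
    dz2: np.ndarray,
    blocks: IDGCNBlocks,
    caches: list[dict],
    spatial_basis: np.ndarray,
    functional_basis: np.ndarray,
) -> tuple[np.ndarray, list[dict]]:
    """Backpropagate through the stack.

    Returns the gradient w.r.t. the shared input x (the two first-block lanes'
    gradients summed) and per-block weight gradients
    ``[{"phi": dW_phi, "omega": dW_omega}, ...]`` in block order.
    """
    grads: list[dict] = [{} for _ in blocks.blocks]
    for idx in range(len(blocks.blocks) - 1, -1, -1):
        b = blocks.blocks[idx]
        cache = caches[idx]
        dy1 = 0.5 * (dz1 - dz2)
        dy2 = 0.5 * (dz1 + dz2)
        # y2 = x2 + omega(y1)
        dx2 = dy2.copy()
        dy1_from_omega, dW_omega = gcn_layer_backward(
            dy2, cache["omega"], functional_basis, b.omega
        )
        dy1 = dy1 + dy1_from_omega
        # y1 = x1 + phi(x2)
        dx1 = dy1
        dx2_from_phi, dW_phi = gcn_layer_backward(dy1, cache["phi"], spatial_basis, b.phi)
        dx2 = dx2 + dx2_from_phi
        grads[idx] = {"phi": dW_phi, "omega": dW_omega}
        dz1, dz2 = dx1, dx2
    return dz1 + dz2, grads
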