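"""Exact invertibility of additive coupling blocks and the block stack."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idgcn.gcn_core import ChebGCNLayerParams
from idgcn.invertible import (
    IDGCNBlocks,
    InvertibleBlockParams,
    _coupling_forward,
    _coupling_inverse,
    block_forward,
    block_inverse,
    stack_forward,
    stack_inverse,
)
from tests.conftest import random_basis, random_layer


def _zero_block(K, f):
    z = ChebGCNLayerParams(np.zeros((K, f, f)))
    return InvertibleBlockParams(phi=z, omega=z)


def _random_blocks(rng, K, f, n_blocks=3, scale=0.3):
    return IDGCNBlocks(
        [
            InvertibleBlockParams(
                phi=random_layer(rng, K, f, scale=scale),
                omega=random_layer(rng, K, f, scale=scale),
            )
            for _ in range(n_blocks)
        ]
    )


def test_zero_functions_closed_form(rng):
    basis = random_basis(rng, 5, 2)
    x1 = rng.normal(size=(5, 3))
    x2 = rng.normal(size=(5, 3))
    z1, z2 = block_forward(x1, x2, _zero_block(2, 3), basis, basis)
    assert np.allclose(z1, 0.5 * (x1 + x2))
    assert np.allclose(z2, 0.5 * (x2 - x1))
    # symmetric first-block input
    z1s, z2s = block_forward(x1, x1, _zero_block(2, 3), basis, basis)
    assert np.allclose(z1s, x1) and np.allclose(z2s, 0.0)
    # inverse of (z1, 0) under zero functions
    a, b = block_inverse(x1, np.zeros_like(x1), _zero_block(2, 3), basis, basis)
    assert np.allclose(a, x1) and np.allclose(b, x1)


def test_block_round_trip_both_ways(rng):
    sp = random_basis(rng, 6, 3)
    fn = random_basis(rng, 6, 3)
    for _ in range(30):
        params = InvertibleBlockParams(
            phi=random_layer(rng, 3, 4), omega=random_layer(rng, 3, 4)
        )
        x1, x2 = rng.normal(size=(2, 6, 4))
        z1, z2 = block_forward(x1, x2, params, sp, fn)
        r1, r2 = block_inverse(z1, z2, params, sp, fn)
        assert max(np.abs(r1 - x1).max(), np.abs(r2 - x2).max()) <= 1e-10
        # compose the other way: inverse then forward
        f1, f2 = block_forward(r1, r2, params, sp, fn)
        assert max(np.abs(f1 - z1).max(), np.abs(f2 - z2).max()) <= 1e-10


def test_single_block_stack_reduces_to_block_forward(rng):
    sp, fn = random_basis(rng, 5, 2), random_basis(rng, 5, 2)
    blocks = _random_blocks(rng, 2, 3, n_blocks=1)
    x = rng.normal(size=(5, 3))
    got = stack_forward(x, blocks, sp, fn)
    want = block_forward(x, x, blocks.blocks[0], sp, fn)
    assert np.allclose(got[0], want[0]) and np.allclose(got[1], want[1])


def test_zero_parameter_stack_matches_mixing_matrix_power(rng):
    """With zero phi/omega each block is the linear lane mixing; its matrix
    power gives the exact multi-block closed form (single block: (x, 0))."""
    sp, fn = random_basis(rng, 5, 2), random_basis(rng, 5, 2)
    x = rng.normal(size=(5, 3))
    mix = 0.5 * np.array([[1.0, 1.0], [-1.0, 1.0]])  # rows: z1, z2 in terms of y1, y2
    for n_blocks in (1, 2, 3):
        blocks = IDGCNBlocks([_zero_block(2, 3) for _ in range(n_blocks)])
        z1, z2 = stack_forward(x, blocks, sp, fn)
        coef = np.linalg.matrix_power(mix, n_blocks) @ np.ones(2)
        assert np.allclose(z1, coef[0] * x, atol=1e-12)
        assert np.allclose(z2, coef[1] * x, atol=1e-12)
        # and the inverse still recovers the input exactly
        r1, r2 = stack_inverse(z1, z2, blocks, sp, fn)
        assert np.allclose(r1, x, atol=1e-12) and np.allclose(r2, x, atol=1e-12)


def test_three_block_stack_round_trip(rng):
    sp, fn = random_basis(rng, 6, 3), random_basis(rng, 6, 3)
    for _ in range(30):
        blocks = _random_blocks(rng, 3, 4)
        x = rng.normal(size=(6, 4))
        z1, z2 = stack_forward(x, blocks, sp, fn)
        r1, r2 = stack_inverse(z1, z2, blocks, sp, fn)
        err = max(np.abs(r1 - x).max(), np.abs(r2 - x).max())
        assert err <= 1e-9


def test_inverse_is_sensitive_to_output_perturbation(rng):
    sp, fn = random_basis(rng, 5, 2), random_basis(rng, 5, 2)
    blocks = _random_blocks(rng, 2, 3)
    x = rng.normal(size=(5, 3))
    z1, z2 = stack_forward(x, blocks, sp, fn)
    clean = stack_inverse(z1, z2, blocks, sp, fn)
    bumped = stack_inverse(z1 + 0.1, z2, blocks, sp, fn)
    assert not np.allclose(clean[0], bumped[0])


@given(seed=st.integers(0, 10_000))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_coupling_invertible_for_arbitrary_nonlinear_functions(seed):
    """Additive coupling inverts exactly for ANY phi/omega, not just GCNs."""
    rng = np.random.default_rng(seed)
    A1, A2 = rng.normal(size=(2, 4, 4))
    b1, b2 = rng.normal(size=(2, 4))

    def phi(v):
        return np.tanh(v @ A1 + b1)

    def omega(v):
        return np.sin(v @ A2) + 0.5 * np.abs(v) + b2

    x1, x2 = rng.normal(size=(2, 5, 4))
    z1, z2 = _coupling_forward(x1, x2, phi, omega)
    r1, r2 = _coupling_inverse(z1, z2, phi, omega)
    assert np.abs(r1 - x1).max() <= 1e-10
    assert np.abs(r2 - x2).max() <= 1e-10


def test_shape_mismatch_rejected(rng):
    sp, fn = random_basis(rng, 5, 2), random_basis(rng, 5, 2)
    blocks = _random_blocks(rng, 2, 3)
    with pytest.raises(ValueError, match="lane shapes"):
        block_forward(np.zeros((5, 3)), np.zeros((4, 3)), blocks.blocks[0], sp, fn)


def test_blocks_must_preserve_feature_dimension():
    with pytest.raises(ValueError, match="preserve the feature dimension"):
        InvertibleBlockParams(
            phi=ChebGCNLayerParams(np.zeros((2, 3, 4))),
            omega=ChebGCNLayerParams(np.zeros((2, 3, 3))),
        )
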