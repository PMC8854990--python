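"""Chebyshev basis identities, layer algebra and the spectral oracle."""

import numpy as np
import pytest

from idgcn.gcn_core import (
    ChebGCNLayerParams,
    chebyshev_basis,
    gcn_layer_forward,
    gcn_layer_forward_cached,
    gcn_layer_backward,
    spectral_oracle_forward,
)
from tests.conftest import random_adjacency, random_basis

from idgcn.graphs import SparseGraph, normalized_laplacian, scaled_laplacian


def test_basis_base_cases(rng):
    lt = rng.normal(size=(5, 5))
    lt = 0.5 * (lt + lt.T)
    T = chebyshev_basis(lt, 1)
    assert T.shape == (1, 5, 5)
    assert np.allclose(T[0], np.eye(5))
    T3 = chebyshev_basis(np.zeros((4, 4)), 3)
    assert np.allclose(T3[0], np.eye(4))
    assert np.allclose(T3[1], 0.0)
    assert np.allclose(T3[2], -np.eye(4))


def test_basis_matches_cosine_identity(rng):
    """T_k(L~) equals cos(k arccos(lambda)) applied eigenvalue-wise."""
    g = SparseGraph(random_adjacency(rng, 6), "functional", 1)
    lap = scaled_laplacian(normalized_laplacian(g))
    T = chebyshev_basis(lap.L_tilde, 4)
    evals, U = np.linalg.eigh(lap.L_tilde)
    lam = np.clip(evals, -1.0, 1.0)
    for k in range(4):
        want = U @ np.diag(np.cos(k * np.arccos(lam))) @ U.T
        assert np.allclose(T[k], want, atol=1e-8)


def test_layer_k1_is_graph_independent(rng):
    basis = random_basis(rng, 6, 1)
    X = rng.normal(size=(6, 3))
    W = rng.normal(size=(1, 3, 2))
    out = gcn_layer_forward(X, basis, ChebGCNLayerParams(W, activation="identity"))
    assert np.allclose(out, X @ W[0], atol=1e-12)


def test_layer_zero_weights_zero_output(rng):
    basis = random_basis(rng, 5, 3)
    X = rng.normal(size=(5, 4))
    out = gcn_layer_forward(X, basis, ChebGCNLayerParams(np.zeros((3, 4, 4))))
    assert np.all(out == 0)


def test_layer_matches_spectral_oracle_over_random_graphs():
    """Polynomial layer with diagonal weights == eigendecomposition route (>=50 graphs)."""
    rng = np.random.default_rng(8)
    worst = 0.0
    for trial in range(60):
        n = int(rng.integers(4, 13))
        K = int(rng.integers(1, 7))
        f = int(rng.integers(1, 4))
        g = SparseGraph(random_adjacency(rng, n), "functional", 1)
        lap = scaled_laplacian(normalized_laplacian(g))
        basis = chebyshev_basis(lap.L_tilde, K)
        betas = rng.normal(size=K)
        W = np.stack([b * np.eye(f) for b in betas])
        X = rng.normal(size=(n, f))
        got = gcn_layer_forward(X, basis, ChebGCNLayerParams(W, activation="identity"))
        want = spectral_oracle_forward(X, lap.L, betas)
        worst = max(worst, np.abs(got - want).max())
    assert worst <= 1e-8


def test_spectral_oracle_identity_filter(rng):
    g = SparseGraph(random_adjacency(rng, 6), "functional", 1)
    lap = normalized_laplacian(g)
    X = rng.normal(size=(6, 2))
    out = spectral_oracle_forward(X, lap.L, [1.0, 0.0, 0.0])
    assert np.allclose(out, X, atol=1e-10)


def test_spectral_oracle_scales_single_eigenvector(rng):
    g = SparseGraph(random_adjacency(rng, 6), "functional", 1)
    lap = scaled_laplacian(normalized_laplacian(g))
    evals, U = np.linalg.eigh(lap.L)
    v = U[:, 2:3]
    betas = np.array([0.3, -0.7, 0.2])
    lam_t = (2.0 / lap.lambda_max) * evals[2] - 1.0
    t0, t1 = 1.0, lam_t
    t2 = 2 * lam_t * t1 - t0
    scale = betas[0] * t0 + betas[1] * t1 + betas[2] * t2
    out = spectral_oracle_forward(v, lap.L, betas)
    assert np.allclose(out, scale * v, atol=1e-9)


def test_layer_permutation_equivariance(rng):
    n, K, f = 7, 3, 4
    basis_lt = random_basis(rng, n, K)
    X = rng.normal(size=(n, f))
    params = ChebGCNLayerParams(rng.normal(size=(K, f, f)))
    out = gcn_layer_forward(X, basis_lt, params)
    perm = rng.permutation(n)
    basis_p = basis_lt[:, np.ix_(perm, perm)[0], np.ix_(perm, perm)[1]]
    out_p = gcn_layer_forward(X[perm], basis_p, params)
    assert np.allclose(out_p, out[perm], atol=1e-10)


def test_layer_gradients_against_central_differences(rng):
    basis = random_basis(rng, 5, 3)
    X = rng.normal(size=(5, 4))
    params = ChebGCNLayerParams(rng.normal(0, 0.5, size=(3, 4, 4)))
    out, cache = gcn_layer_forward_cached(X, basis, params)
    dOut = rng.normal(size=out.shape)
    dX, dW = gcn_layer_backward(dOut, cache, basis, params)
    h = 1e-6

    def loss(x, w):
        p = ChebGCNLayerParams(w, activation=params.activation)
        return float(np.sum(gcn_layer_forward(x, basis, p) * dOut))

    for arr, grad, which in ((X, dX, "x"), (params.weights, dW, "w")):
        flat = arr.ravel()
        for i in np.random.default_rng(0).choice(flat.size, 15, replace=False):
            orig = flat[i]
            flat[i] = orig + h
            lp = loss(X, params.weights)
            flat[i] = orig - h
            lm = loss(X, params.weights)
            flat[i] = orig
            num = (lp - lm) / (2 * h)
            ana = grad.ravel()[i]
            assert abs(num - ana) / max(1e-8, abs(num) + abs(ana)) < 1e-4, which


def test_shape_mismatch_errors(rng):
    basis = random_basis(rng, 5, 3)
    with pytest.raises(ValueError, match="feature dimension"):
        gcn_layer_forward(rng.normal(size=(5, 3)), basis, ChebGCNLayerParams(np.zeros((3, 4, 4))))
    with pytest.raises(ValueError, match="orders"):
        gcn_layer_forward(rng.normal(size=(5, 4)), basis, ChebGCNLayerParams(np.zeros((2, 4, 4))))
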