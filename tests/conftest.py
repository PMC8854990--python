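import numpy as np
import pytest

from idgcn.gcn_core import ChebGCNLayerParams, chebyshev_basis
from idgcn.graphs import SparseGraph, normalized_laplacian, scaled_laplacian
from idgcn.synthetic_data import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_adjacency(rng, n):
    a = rng.random((n, n))
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 0.0)
    return a


def random_basis(rng, n, K):
    """Chebyshev basis of a random weighted graph's rescaled Laplacian."""
    g = SparseGraph(random_adjacency(rng, n), "functional", 1)
    lap = scaled_laplacian(normalized_laplacian(g))
    return chebyshev_basis(lap.L_tilde, K)


def random_layer(rng, K, f, activation="relu", scale=0.3):
    return ChebGCNLayerParams(rng.normal(0.0, scale, size=(K, f, f)), activation=activation)


@pytest.fixture(scope="session")
def small_separated_cohort():
    """Tiny separated cohort shared by fast end-to-end tests."""
    return generate_cohort(
        CohortSpec(
            n_subjects_per_class=15,
            n_rois=10,
            n_timepoints=100,
            informative_edges=[(0, 1), (2, 3)],
            static_effect=0.6,
            seed=99,
        )
    )
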