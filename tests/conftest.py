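import numpy as np
import pytest

from covgraph.graphs import (
    WeightedGraph,
    make_chain_graph,
    make_cluster_graph,
    make_hub_graph,
    make_scale_free_graph,
)
from covgraph.synthetic import correlation_from_graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def star3():
    """3-node star with hub 0 and weights 0.4 on both edges."""
    A = np.zeros((3, 3))
    A[0, 1] = A[1, 0] = 0.4
    A[0, 2] = A[2, 0] = 0.4
    return A


@pytest.fixture
def chain50():
    return make_chain_graph(50)


@pytest.fixture
def chain50_model(chain50):
    return correlation_from_graph(chain50, w=0.5, eps=0.1)


def random_structure(p, rng, target_radius=0.6):
    """Random symmetric zero-diagonal matrix scaled to a given spectral radius."""
    A = rng.uniform(-1, 1, (p, p))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    sr = np.max(np.abs(np.linalg.eigvals(A)))
    return A * (target_radius / sr)


@pytest.fixture
def benchmark_graphs():
    return {
        "chain": make_chain_graph(50),
        "cluster": make_cluster_graph(50, 5, 0.3, seed=7),
        "scale_free": make_scale_free_graph(50, seed=7),
        "hub": make_hub_graph(50, 10),
    }
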