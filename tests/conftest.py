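import numpy as np
import pytest

from fconn.cohort import CohortSpec
from fconn.network import WeightedNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """Small cohort used by pipeline-level tests."""
    return CohortSpec(
        n_patients=6, n_controls=6, n_rois=24,
        module_sizes=(8, 6, 6, 4), n_volumes=80, seed=7,
    )


def random_weighted_network(n, density, rng):
    """Random symmetric positive-weighted graph for oracle comparisons."""
    a = rng.random((n, n))
    mask = np.triu(rng.random((n, n)) < density, k=1)
    a = np.where(mask, a, 0.0)
    a = a + a.T
    return WeightedNetwork.from_matrix(a)


def floyd_warshall_oracle(net):
    """Brute-force all-pairs shortest paths over lengths 1/weight."""
    n = net.n_nodes
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i, j, w in zip(net.i, net.j, net.w):
        d[i, j] = d[j, i] = 1.0 / w
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def efficiency_oracle(d):
    """Direct-formula global efficiency from a distance matrix."""
    n = d.shape[0]
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                acc += 1.0 / d[i, j]
    return acc / (n * (n - 1))
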