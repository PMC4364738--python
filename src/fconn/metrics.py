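"""Weighted efficiency metrics with reciprocal-weight edge lengths.

The length of an edge is the reciprocal of its weight, interpreting a high
correlation as a short functional distance.  Global efficiency is the mean
of inverse shortest path lengths over ordered node pairs; nodal efficiency
is the per-node analogue; local efficiency averages, over nodes, the global
efficiency of each node's neighbor-induced subgraph.  Disconnected pairs
contribute 0 (1/inf), keeping every metric finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse import csgraph

from .network import WeightedNetwork

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "shortest_paths",
    "global_efficiency",
    "local_efficiency",
    "nodal_efficiency",
    "compute_global_metrics",
]


@dataclass
class GlobalMetrics:
    e_glob: float
    e_loc: float
    e_glob_norm: float | None = None
    e_loc_norm: float | None = None


@dataclass
class NodalMetrics:
    e_nodal: np.ndarray
    strength: np.ndarray


def _length_csr(net: WeightedNetwork):
    inv = WeightedNetwork(net.n_nodes, net.i, net.j, 1.0 / net.w)
    return inv.to_sparse()


def shortest_paths(net: WeightedNetwork) -> np.ndarray:
    """All-pairs shortest path lengths over edge lengths 1/weight.

    Unreachable pairs are +inf; the diagonal is 0.
    """
    if net.k == 0:
        d = np.full((net.n_nodes, net.n_nodes), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    return csgraph.shortest_path(_length_csr(net), method="auto", directed=False)


def _efficiency_from_d(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(net: WeightedNetwork) -> float:
    """Mean of 1/d_ij over all ordered pairs i != j."""
    if net.n_nodes < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    return _efficiency_from_d(shortest_paths(net))


def _induced_subgraph(net: WeightedNetwork, nodes: np.ndarray) -> WeightedNetwork:
    """Subgraph on `nodes` retaining original weights between them."""
    idx = -np.ones(net.n_nodes, dtype=np.intp)
    idx[nodes] = np.arange(len(nodes))
    keep = (idx[net.i] >= 0) & (idx[net.j] >= 0)
    return WeightedNetwork(len(nodes), idx[net.i[keep]], idx[net.j[keep]], net.w[keep])


def local_efficiency(net: WeightedNetwork) -> float:
    """Average over nodes of the global efficiency of the neighbor subgraph.

    Nodes with fewer than 2 neighbors contribute 0.
    """
    if net.n_nodes < 1:
        raise ValueError("empty network")
    a = net.to_matrix()
    with np.errstate(divide="ignore"):
        lengths = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return float(_local_efficiency_kernel(lengths))


@njit(cache=True)
def _fw_efficiency(d):  # pragma: no cover - jitted
    """In-place Floyd–Warshall, then the mean of inverse distances."""
    n = d.shape[0]
    for k in range(n):
        for i in range(n):
            dik = d[i, k]
            if dik == np.inf:
                continue
            for j in range(n):
                alt = dik + d[k, j]
                if alt < d[i, j]:
                    d[i, j] = alt
    if n < 2:
        return 0.0
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and d[i, j] < np.inf and d[i, j] > 0:
                acc += 1.0 / d[i, j]
    return acc / (n * (n - 1))


@njit(cache=True)
def _local_efficiency_kernel(lengths):  # pragma: no cover - jitted
    n = lengths.shape[0]
    total = 0.0
    idx = np.empty(n, np.int64)
    for i in range(n):
        m = 0
        for j in range(n):
            if j != i and lengths[i, j] != np.inf:
                idx[m] = j
                m += 1
        if m < 2:
            continue
        d = np.empty((m, m))
        for p in range(m):
            for q in range(m):
                d[p, q] = lengths[idx[p], idx[q]]
            d[p, p] = 0.0
        total += _fw_efficiency(d)
    return total / n


def nodal_efficiency(net: WeightedNetwork) -> NodalMetrics:
    """Per-node mean of 1/d_ij over the other nodes, plus nodal strength.

    The node-average of nodal efficiency equals global efficiency exactly.
    """
    if net.n_nodes < 2:
        raise ValueError("nodal efficiency requires at least 2 nodes")
    d = shortest_paths(net)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    e = inv.sum(axis=1) / (net.n_nodes - 1)
    return NodalMetrics(e_nodal=e, strength=net.strengths())


def compute_global_metrics(net: WeightedNetwork) -> GlobalMetrics:
    return GlobalMetrics(e_glob=global_efficiency(net), e_loc=local_efficiency(net))
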