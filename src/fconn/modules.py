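"""Module detection by spectral modularity optimization.

Modularity of a partition p of a weighted network is

    Q(p) = sum_s [ w_s / W - (W_s / 2W)^2 ]

where W is the total edge weight (each edge counted once), w_s the weight
inside module s, and W_s the summed nodal strength of module s (each
incident edge counted at both endpoints).  Modules are found by recursive
leading-eigenvector bisection of the modularity matrix with greedy
single-node fine-tuning after each split, stopping when no split increases
Q.  Connected components are partitioned independently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csgraph

from .metrics import GlobalMetrics, _induced_subgraph, global_efficiency, local_efficiency
from .network import WeightedNetwork
from .nulls import normalized_efficiencies

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "modularity_q",
    "spectral_partition",
    "module_connectivity",
    "module_level_metrics",
    "partitions_equivalent",
]


@dataclass
class Partition:
    labels: np.ndarray
    n_modules: int
    q: float
    w_s: np.ndarray
    strength_s: np.ndarray
    total_weight: float

    def module_nodes(self, s: int) -> np.ndarray:
        return np.flatnonzero(self.labels == s)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_modules)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 0..m-1 in order of first appearance."""
    _, canon = np.unique(labels, return_inverse=True)
    first = {}
    out = np.empty_like(canon)
    nxt = 0
    for k, lab in enumerate(canon):
        if lab not in first:
            first[lab] = nxt
            nxt += 1
        out[k] = first[lab]
    return out


def modularity_q(net: WeightedNetwork, labels: np.ndarray) -> Partition:
    """Evaluate Q for given module labels (see module docstring)."""
    labels = _canonical_labels(np.asarray(labels))
    if labels.size != net.n_nodes:
        raise ValueError("labels must cover all nodes")
    total = float(net.w.sum())
    if total == 0:
        raise ValueError("network has zero total weight")
    m = labels.max() + 1
    intra = labels[net.i] == labels[net.j]
    w_s = np.bincount(labels[net.i[intra]], weights=net.w[intra], minlength=m)
    strength_s = np.bincount(labels, weights=net.strengths(), minlength=m)
    q = float(np.sum(w_s / total - (strength_s / (2 * total)) ** 2))
    return Partition(labels=labels, n_modules=int(m), q=q, w_s=w_s,
                     strength_s=strength_s, total_weight=total)


def _modularity_matrix(a: np.ndarray, total: float) -> np.ndarray:
    k = a.sum(axis=1)
    return a - np.outer(k, k) / (2.0 * total)


def _fine_tune(b_g: np.ndarray, s: np.ndarray, max_passes: int = 200) -> np.ndarray:
    """Greedy single-node sign flips while any flip increases s^T B s."""
    s = s.copy()
    bs = b_g @ s
    diag = np.diag(b_g)
    for _ in range(max_passes):
        gains = diag - s * bs  # proportional to change in s^T B s / 4
        best = int(np.argmax(gains))
        if gains[best] <= 1e-12:
            break
        s[best] = -s[best]
        bs += 2.0 * s[best] * b_g[:, best]
    return s


def _bisect(b_g: np.ndarray, total: float) -> tuple[np.ndarray, float] | None:
    """Attempt one bisection; return (bool mask, delta_q) or None if indivisible."""
    n = b_g.shape[0]
    if n < 2:
        return None
    vals, vecs = np.linalg.eigh((b_g + b_g.T) / 2.0)
    v = vecs[:, -1]
    nz = np.flatnonzero(np.abs(v) > 1e-12)
    if nz.size and v[nz[0]] < 0:
        v = -v
    s = np.where(v >= 0, 1.0, -1.0)
    s = _fine_tune(b_g, s)
    if np.all(s == s[0]):
        return None
    dq = float(s @ b_g @ s) / (4.0 * total)
    if dq <= 1e-12:
        return None
    return s > 0, dq


def spectral_partition(net: WeightedNetwork) -> Partition:
    """Recursive leading-eigenvector community detection (deterministic).

    Eigenvector sign ambiguity is resolved by forcing the first nonzero
    component positive, so repeated runs give identical partitions.
    """
    n = net.n_nodes
    a = net.to_matrix()
    total = float(net.w.sum())
    if total == 0:
        raise ValueError("network has zero total weight")
    labels = np.zeros(n, dtype=np.intp)
    n_comp, comp = csgraph.connected_components(net.to_sparse(), directed=False)
    next_label = 0
    b_full = _modularity_matrix(a, total)
    stack: list[np.ndarray] = []
    for c in range(n_comp):
        stack.append(np.flatnonzero(comp == c))
    groups: list[np.ndarray] = []
    while stack:
        nodes = stack.pop()
        if nodes.size < 2:
            groups.append(nodes)
            continue
        b_g = b_full[np.ix_(nodes, nodes)]
        b_g = b_g - np.diag(b_g.sum(axis=1))  # generalized matrix for subdivision
        res = _bisect(b_g, total)
        if res is None:
            groups.append(nodes)
        else:
            mask, _ = res
            stack.append(nodes[mask])
            stack.append(nodes[~mask])
    for g in groups:
        labels[g] = next_label
        next_label += 1
    return modularity_q(net, labels)


def partitions_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff two labelings induce the same partition up to relabeling."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    return bool(np.array_equal(_canonical_labels(a), _canonical_labels(b)))


def module_connectivity(
    nets: dict[str, WeightedNetwork],
    partition: Partition,
) -> pd.DataFrame:
    """Per-subject mean intra- and inter-module edge weight.

    The mean runs over all *possible* node pairs within/between modules, so
    absent (sub-threshold) edges count as 0.  Columns are ``intra_<s>`` and
    ``inter_<s>_<t>``.
    """
    m = partition.n_modules
    sizes = partition.sizes
    rows = {}
    for sid, net in nets.items():
        a = net.to_matrix()
        row = {}
        for s in range(m):
            ns = partition.module_nodes(s)
            denom = sizes[s] * (sizes[s] - 1) / 2
            row[f"intra_{s}"] = a[np.ix_(ns, ns)].sum() / 2 / denom if denom else 0.0
        for s in range(m):
            for t in range(s + 1, m):
                ns, nt = partition.module_nodes(s), partition.module_nodes(t)
                denom = sizes[s] * sizes[t]
                row[f"inter_{s}_{t}"] = a[np.ix_(ns, nt)].sum() / denom if denom else 0.0
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def module_level_metrics(
    net: WeightedNetwork,
    partition: Partition,
    rng: np.random.Generator,
    n_nulls: int = 100,
) -> dict[int, GlobalMetrics]:
    """Efficiencies (raw + normalized) of each module's induced subgraph.

    Modules with fewer than 3 nodes are skipped with a warning.
    """
    out: dict[int, GlobalMetrics] = {}
    for s in range(partition.n_modules):
        nodes = partition.module_nodes(s)
        if nodes.size < 3:
            warnings.warn(f"module {s} has < 3 nodes; skipped", stacklevel=2)
            continue
        sub = _induced_subgraph(net, nodes)
        if sub.k < 2:
            out[s] = GlobalMetrics(
                e_glob=global_efficiency(sub) if sub.n_nodes >= 2 else 0.0,
                e_loc=local_efficiency(sub),
            )
            continue
        out[s] = normalized_efficiencies(sub, rng, n_nulls=n_nulls)
    return out
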