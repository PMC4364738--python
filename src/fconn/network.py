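"""Construction of sparse, positive, weighted functional networks.

Individual networks are built by Pearson-correlating ROI time series,
keeping only edges whose correlations survive a Bonferroni-corrected
significance threshold, and discarding negative correlations.  Group-level
networks are formed by Fisher r-to-z averaging, and a backbone is extracted
with a locally adaptive sparsification filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse import csgraph

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "WeightedNetwork",
    "pearson_connectivity",
    "threshold_to_weighted_network",
    "group_mean_network",
    "extract_backbone",
    "seed_connectivity_map",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric matrix of pairwise Pearson correlations between ROIs.

    The diagonal carries no information (self-correlation) and is ignored by
    every consumer.  ``n_effective_timepoints`` is recorded so that edge
    significance can be assessed downstream with ``df = n - 2``.
    """

    r: np.ndarray
    n_effective_timepoints: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.r, self.r.T, atol=1e-12, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")

    @property
    def n_rois(self) -> int:
        return self.r.shape[0]


@dataclass
class WeightedNetwork:
    """Undirected graph with strictly positive edge weights.

    Edges are stored as parallel arrays ``(i, j, w)`` with ``i < j``; node
    ids are 0-based.  This is the shared currency of the efficiency,
    null-model and modularity machinery.
    """

    n_nodes: int
    i: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    j: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    w: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=np.intp)
        self.j = np.asarray(self.j, dtype=np.intp)
        self.w = np.asarray(self.w, dtype=float)
        if not (self.i.shape == self.j.shape == self.w.shape):
            raise ValueError("edge arrays must have identical shape")
        if self.i.size:
            if np.any(self.i == self.j):
                raise ValueError("self-loops are not allowed")
            lo = np.minimum(self.i, self.j)
            hi = np.maximum(self.i, self.j)
            self.i, self.j = lo, hi
            order = np.lexsort((self.j, self.i))
            self.i, self.j, self.w = self.i[order], self.j[order], self.w[order]
            keys = self.i * self.n_nodes + self.j
            if np.unique(keys).size != keys.size:
                raise ValueError("duplicate edges")
            if np.any(self.w <= 0):
                raise ValueError("weights must be strictly positive")
            if self.j.max() >= self.n_nodes:
                raise ValueError("node id out of range")

    @property
    def k(self) -> int:
        """Number of edges (K)."""
        return int(self.w.size)

    def to_matrix(self) -> np.ndarray:
        """Dense symmetric adjacency matrix with zeros for absent edges."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        a[self.i, self.j] = self.w
        a[self.j, self.i] = self.w
        return a

    def to_sparse(self) -> sparse.csr_matrix:
        n = self.n_nodes
        rows = np.concatenate([self.i, self.j])
        cols = np.concatenate([self.j, self.i])
        vals = np.concatenate([self.w, self.w])
        return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=np.intp)
        np.add.at(d, self.i, 1)
        np.add.at(d, self.j, 1)
        return d

    def strengths(self) -> np.ndarray:
        s = np.zeros(self.n_nodes)
        np.add.at(s, self.i, self.w)
        np.add.at(s, self.j, self.w)
        return s

    @classmethod
    def from_matrix(cls, a: np.ndarray) -> "WeightedNetwork":
        """Build from a symmetric matrix, keeping strictly positive entries."""
        a = np.asarray(a, dtype=float)
        iu, ju = np.triu_indices(a.shape[0], k=1)
        mask = a[iu, ju] > 0
        return cls(a.shape[0], iu[mask], ju[mask], a[iu, ju][mask])


def pearson_connectivity(ts: np.ndarray) -> ConnectivityMatrix:
    """Pearson correlation matrix of ROI time series (columns = ROIs).

    Constant columns have undefined correlations; these are set to 0 with a
    warning rather than propagating NaN.  NaNs in the input are an error.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("need a 2-D array with at least 3 time points")
    if np.isnan(ts).any():
        raise ValueError("input time series contain NaNs")
    constant = ts.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant ROI column(s); correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts, rowvar=False)
    r = np.asarray(r, dtype=float)
    r[np.isnan(r)] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r=r, n_effective_timepoints=ts.shape[0])


def bonferroni_edge_threshold(n_rois: int, alpha: float = 0.05) -> float:
    """Per-edge significance level: alpha over the M = n(n-1)/2 unique pairs."""
    m = n_rois * (n_rois - 1) // 2
    return alpha / m


def r_to_p(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p-value of a Pearson r via the t transform with given df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    return 2.0 * stats.t.sf(t, df)


def threshold_to_weighted_network(
    cm: ConnectivityMatrix,
    alpha: float = 0.05,
    df_override: int | None = None,
) -> WeightedNetwork:
    """Bonferroni-threshold a correlation matrix into a positive weighted net.

    An edge (i, j) is retained when its two-sided p-value (t transform of r
    with ``df = n_effective_timepoints - 2``) falls below ``alpha / M`` with
    ``M = n(n-1)/2``, and its correlation is strictly positive.  Surviving
    correlations become edge weights.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = df_override if df_override is not None else cm.n_effective_timepoints - 2
    if df <= 2:
        raise ValueError("degrees of freedom must exceed 2")
    n = cm.n_rois
    iu, ju = np.triu_indices(n, k=1)
    r = cm.r[iu, ju]
    p = r_to_p(r, df)
    keep = (p < bonferroni_edge_threshold(n, alpha)) & (r > 0)
    return WeightedNetwork(n, iu[keep], ju[keep], r[keep])


def group_mean_network(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Fisher z-average a list of correlation matrices.

    Each matrix is r-to-z transformed (atanh), the z matrices are averaged
    elementwise, and the mean is transformed back (tanh).  Off-diagonal
    entries at exactly +/-1 are clipped to +/-0.999999 with a warning.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    n = matrices[0].n_rois
    if any(m.n_rois != n for m in matrices):
        raise ValueError("matrices must share n_rois")
    acc = np.zeros((n, n))
    mask_diag = np.eye(n, dtype=bool)
    for m in matrices:
        r = m.r.copy()
        off = ~mask_diag
        if np.any(np.abs(r[off]) >= 1.0):
            warnings.warn("off-diagonal |r| = 1 clipped to 0.999999", stacklevel=2)
            r[off] = np.clip(r[off], -0.999999, 0.999999)
        acc += np.arctanh(np.where(mask_diag, 0.0, r))
    z_mean = acc / len(matrices)
    r_mean = np.tanh(z_mean)
    np.fill_diagonal(r_mean, 1.0)
    n_eff = int(round(np.mean([m.n_effective_timepoints for m in matrices])))
    return ConnectivityMatrix(r=r_mean, n_effective_timepoints=n_eff)


def network_to_connectivity(net: WeightedNetwork, n_effective_timepoints: int) -> ConnectivityMatrix:
    """View a thresholded network as a correlation matrix (absent edges = 0)."""
    return ConnectivityMatrix(r=net.to_matrix() + np.eye(net.n_nodes),
                              n_effective_timepoints=n_effective_timepoints)


def _local_edge_pvalues(a: np.ndarray) -> np.ndarray:
    """Node-local empirical p for every positive entry of a dense matrix.

    For node i with k incident positive weights, the p-value of an incident
    edge of weight w is the fraction of i's incident weights strictly larger
    than w — 0 for the node's top-ranked edge(s).
    """
    n = a.shape[0]
    p = np.full((n, n), np.inf)
    for i in range(n):
        wi = a[i]
        pos = wi > 0
        k = int(pos.sum())
        if k == 0:
            continue
        vals = wi[pos]
        # strict rank: count of strictly greater incident weights
        greater = (vals[None, :] > vals[:, None]).sum(axis=1)
        p[i, pos] = greater / k
    return p


def extract_backbone(cm: ConnectivityMatrix, local_alpha: float = 0.05) -> WeightedNetwork:
    """Locally adaptive sparsification of a group-level correlation matrix.

    Keeps edge (i, j) when it ranks within the top ``local_alpha`` fraction
    of the incident positive weights of node i OR node j (strict-rank
    empirical p, so ties at a node's maximum are always kept).  If the
    result is connected on fewer than 95% of nodes, ``local_alpha`` is
    doubled with a logged warning until connectivity is reached or all
    positive edges are kept.
    """
    a = cm.r.copy()
    np.fill_diagonal(a, 0.0)
    a[a < 0] = 0.0
    if not np.any(a > 0):
        raise ValueError("matrix has no positive off-diagonal entries")
    p = _local_edge_pvalues(a)
    n = cm.n_rois
    iu, ju = np.triu_indices(n, k=1)
    pos = a[iu, ju] > 0
    alpha = local_alpha
    while True:
        keep = pos & ((p[iu, ju] <= alpha) | (p[ju, iu] <= alpha))
        net = WeightedNetwork(n, iu[keep], ju[keep], a[iu, ju][keep])
        n_comp, labels = csgraph.connected_components(net.to_sparse(), directed=False)
        largest = np.bincount(labels).max() if n else 0
        if largest >= 0.95 * n or alpha >= 1.0:
            if largest < 0.95 * n:
                logger.warning(
                    "backbone still spans only %d/%d nodes with all positive edges kept",
                    largest, n,
                )
            return net
        alpha = min(1.0, alpha * 2)
        logger.warning(
            "backbone connected on %d/%d nodes; relaxing local_alpha to %g",
            largest, n, alpha,
        )


def seed_connectivity_map(ts: np.ndarray, seed_roi: int) -> np.ndarray:
    """Pearson r of one seed ROI's time series against every ROI (self = 1)."""
    ts = np.asarray(ts, dtype=float)
    if not 0 <= seed_roi < ts.shape[1]:
        raise ValueError("seed_roi out of range")
    seed = ts[:, seed_roi]
    if seed.std() == 0:
        raise ValueError("seed time series is constant")
    sc = seed - seed.mean()
    x = ts - ts.mean(axis=0)
    denom = np.sqrt((sc**2).sum()) * np.sqrt((x**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x.T @ sc) / denom
    r[np.isnan(r)] = 0.0
    r[seed_roi] = 1.0
    return np.clip(r, -1.0, 1.0)
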