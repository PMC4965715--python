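"""Recursive spectral bisection of PPI networks.

A connected (sub)graph is split by the eigenvector x* at the smallest
positive eigenvalue of the generalized problem

    Q x = lambda D x,

where Q = D - A is the graph Laplacian of the induced subgraph and D its
degree diagonal.  The two sides are chosen by deterministic 1-D 2-means
on the components of x*.  A block is split again only while the
resulting two-way objective value (normalized cut by default) stays
below ``split_threshold``; the recursion therefore adapts the number,
size and density of clusters to the network topology rather than taking
them as parameters.

Disconnected node sets are always separated into connected components
before any eigenproblem is solved, so the pencil (Q, D) the solver sees
is always that of a connected graph (D positive definite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, ClusterMixin

from . import objectives
from .network_io import PPINetwork, as_network

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralConfig",
    "laplacian_pair",
    "fiedler_vector",
    "bisect",
    "recursive_spectral_clustering",
    "RecursiveSpectralClustering",
]

_TWO_WAY = {
    "minmax": objectives.minmax_cut,
    "ratio": objectives.ratio_cut,
    "normalized": objectives.normalized_cut,
}


@dataclass
class SpectralConfig:
    """Knobs of the recursive bisection.

    objective:
        Two-way score used to decide whether an attempted split is kept
        (``normalized`` by default: the eigenproblem Qx = lambda Dx is
        its relaxation).
    split_threshold:
        A block is split while the achieved objective value is below
        this (default 1.0 for the normalized cut, whose value on a
        covering bipartition lies in [0, 2]).
    min_cluster_size:
        Splits producing a side smaller than this are rejected.
    eig_tol:
        Residual tolerance for the eigensolver.
    """

    objective: str = "normalized"
    split_threshold: float = 1.0
    min_cluster_size: int = 1
    eig_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.objective not in _TWO_WAY:
            raise ValueError(f"objective must be one of {sorted(_TWO_WAY)}")
        if self.split_threshold <= 0:
            raise ValueError("split_threshold must be positive")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


def _ordered(net: PPINetwork, nodes) -> list:
    return sorted(nodes, key=net.index.__getitem__)


def laplacian_pair(net: PPINetwork, nodes) -> tuple[np.ndarray, np.ndarray]:
    """(Q, D) of the induced subgraph, nodes ordered by network index.

    Q = D - A is positive semidefinite with zero row sums; D holds the
    induced (within-subgraph) degrees.
    """
    order = _ordered(net, nodes)
    if len(order) < 2:
        raise ValueError("need at least 2 nodes to form a Laplacian")
    pos = {v: i for i, v in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for u, v, d in net.graph.subgraph(order).edges(data=True):
        w = d.get("weight", 1.0)
        A[pos[u], pos[v]] = w
        A[pos[v], pos[u]] = w
    deg = A.sum(axis=1)
    if not deg.any():
        raise ValueError("subgraph has no edges; unsplittable")
    return np.diag(deg) - A, np.diag(deg)


def fiedler_vector(Q: np.ndarray, D: np.ndarray, eig_tol: float = 1e-8) -> np.ndarray:
    """Generalized eigenvector at the smallest positive eigenvalue of Qx = lambda Dx.

    Assumes a connected subgraph (so lambda_1 = 0 is simple and the
    target eigenvalue is the second-smallest).  The vector is
    D-normalized and its sign fixed so the first nonzero component is
    positive.
    """
    vals, vecs = scipy.linalg.eigh(Q, D, subset_by_index=[1, 1])
    lam, x = float(vals[0]), vecs[:, 0]
    residual = float(np.linalg.norm(Q @ x - lam * (D @ x)))
    scale = max(1.0, float(np.linalg.norm(Q @ x)))
    if residual > max(eig_tol, 1e-10) * scale * 100:
        raise RuntimeError(
            f"eigensolver residual {residual:.3e} exceeds tolerance {eig_tol:.1e}"
        )
    if lam <= 1e-12:
        raise RuntimeError("no positive eigenvalue found; subgraph disconnected?")
    norm = float(np.sqrt(x @ (D @ x)))
    if norm > 0:
        x = x / norm
    for comp in x:
        if comp != 0:
            if comp < 0:
                x = -x
            break
    return x


def _two_means_1d(values: np.ndarray) -> np.ndarray | None:
    """Deterministic 1-D 2-means: centroids start at min and max.

    Returns a boolean mask (True = upper-centroid side) or None when the
    values are all equal (no split direction).  Ties in assignment break
    toward the lower-mean centroid.
    """
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return None
    upper = values > (lo + hi) / 2.0  # tie -> lower side
    for _ in range(200):
        c_lo = values[~upper].mean()
        c_hi = values[upper].mean()
        new_upper = np.abs(values - c_hi) < np.abs(values - c_lo)  # tie -> lower
        # keep extremes anchored so neither side empties
        new_upper[np.argmin(values)] = False
        new_upper[np.argmax(values)] = True
        if np.array_equal(new_upper, upper):
            break
        upper = new_upper
    return upper


def bisect(net: PPINetwork, nodes, config: SpectralConfig | None = None) -> tuple[set, set]:
    """Split a node set in two.

    Disconnected sets are split along connected components (first
    component vs. the rest); connected sets via the Fiedler vector and
    1-D 2-means.  A constant eigenvector falls back to an index-parity
    split (logged).
    """
    config = config or SpectralConfig()
    nodes = set(nodes)
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes to bisect")
    sub = net.graph.subgraph(nodes)
    comps = sorted(nx.connected_components(sub), key=lambda c: min(net.index[v] for v in c))
    if len(comps) > 1:
        v1 = set(comps[0])
        return v1, nodes - v1
    order = _ordered(net, nodes)
    Q, D = laplacian_pair(net, nodes)
    x = fiedler_vector(Q, D, config.eig_tol)
    upper = _two_means_1d(x)
    if upper is None:
        logger.warning("constant Fiedler vector; falling back to index-parity split")
        v1 = {v for i, v in enumerate(order) if i % 2 == 0}
        return v1, nodes - v1
    v1 = {v for v, up in zip(order, upper) if not up}
    return v1, nodes - v1


def _split_recursively(net: PPINetwork, config: SpectralConfig) -> list:
    objective_fn = _TWO_WAY[config.objective]
    accepted: list = []
    stack: list = [set(net.proteins)]
    while stack:
        nodes = stack.pop()
        if len(nodes) > 1:
            sub = net.graph.subgraph(nodes)
            comps = sorted(
                nx.connected_components(sub),
                key=lambda c: min(net.index[v] for v in c),
            )
            if len(comps) > 1:
                stack.extend(reversed([set(c) for c in comps]))
                continue
        if len(nodes) < 2 or len(nodes) < 2 * config.min_cluster_size:
            accepted.append(nodes)
            continue
        v1, v2 = bisect(net, nodes, config)
        value = objective_fn(net, v1, v2)
        if value < config.split_threshold and min(len(v1), len(v2)) >= config.min_cluster_size:
            stack.append(v2)
            stack.append(v1)
        else:
            accepted.append(nodes)
    accepted.sort(key=lambda c: min(net.index[v] for v in c))
    return accepted


class RecursiveSpectralClustering(ClusterMixin, BaseEstimator):
    """Exclusive graph clustering by recursive spectral bisection.

    Accepts a PPINetwork, a networkx graph, or a symmetric adjacency
    matrix.  Fitted attributes: ``clusters_`` (list of frozensets of
    node identifiers), ``labels_`` (cluster index per node, in network
    node order) and ``n_clusters_``.  The procedure is deterministic:
    identical inputs yield identical clusterings.
    """

    def __init__(
        self,
        objective: str = "normalized",
        split_threshold: float = 1.0,
        min_cluster_size: int = 1,
        eig_tol: float = 1e-8,
    ):
        self.objective = objective
        self.split_threshold = split_threshold
        self.min_cluster_size = min_cluster_size
        self.eig_tol = eig_tol

    def _config(self) -> SpectralConfig:
        return SpectralConfig(
            objective=self.objective,
            split_threshold=self.split_threshold,
            min_cluster_size=self.min_cluster_size,
            eig_tol=self.eig_tol,
        )

    def fit(self, X, y=None):
        net = as_network(X)
        if net.n_proteins == 0:
            raise ValueError("empty network")
        blocks = _split_recursively(net, self._config())
        self.network_ = net
        self.clusters_ = [frozenset(b) for b in blocks]
        self.n_clusters_ = len(blocks)
        labels = np.empty(net.n_proteins, dtype=int)
        for ci, block in enumerate(blocks):
            for v in block:
                labels[net.index[v]] = ci
        self.labels_ = labels
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_


def recursive_spectral_clustering(net: PPINetwork, config: SpectralConfig | None = None):
    """Partition the whole network; thin wrapper over the estimator."""
    from .ga import Clustering

    config = config or SpectralConfig()
    est = RecursiveSpectralClustering(
        objective=config.objective,
        split_threshold=config.split_threshold,
        min_cluster_size=config.min_cluster_size,
        eig_tol=config.eig_tol,
    ).fit(net)
    return Clustering([set(c) for c in est.clusters_])
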