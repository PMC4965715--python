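"""Cut-based and density-based objective functions for graph clusterings.

Two-way objectives (min-max cut JM, ratio cut JR, normalized cut JN)
score a bipartition (V1, V2) of a (sub)graph and are *minimized*:

    JM = W12/W11 + W12/W22
    JR = W12/|V1| + W12/|V2|
    JN = W12/d1  + W12/d2

where W12 is the cut weight, W_kk the internal edge weight of side k and
d_k its degree mass *within the scored subgraph* (so recursive bisection
is self-similar).

The density fitness JD scores a whole (possibly overlapping) clustering
and is *maximized*:

    JD = sum_k  W_kk / (A_k + W_ki)

with A_k = |C_k|(|C_k|-1)/2 the maximum possible number of internal
edges and W_ki the number of boundary edges (exactly one endpoint in
C_k).  Each term lies in [0, 1]; a perfectly isolated clique scores 1.

Multiway versions of the three cut objectives (sum of per-cluster
boundary/denominator terms, negated so that higher is better) are
provided so every objective can drive the genetic algorithm uniformly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable

from .network_io import PPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterStats",
    "cluster_stats",
    "cut_weight",
    "minmax_cut",
    "ratio_cut",
    "normalized_cut",
    "density_fitness",
    "multiway_cut_fitness",
    "get_objective",
    "OBJECTIVES",
]

OBJECTIVES = ("density", "minmax", "ratio", "normalized")


@dataclass(frozen=True)
class ClusterStats:
    """Per-cluster edge statistics (degrees taken in the full network)."""

    size: int
    w_internal: float      # W_kk: edge weight inside the cluster
    w_boundary: float      # W_ki: weight of edges with exactly one endpoint inside
    max_internal: float    # A_k = size*(size-1)/2
    degree_mass: float     # d_k = sum of whole-network degrees of members


def _clusters_of(clustering) -> list:
    return list(getattr(clustering, "clusters", clustering))


def _internal_weight(net: PPINetwork, nodes: set) -> float:
    """Total weight of edges with both endpoints in ``nodes``."""
    if net.weighted:
        g = net.graph
        total = 0.0
        for v in nodes:
            for u, d in g.adj[v].items():
                if u in nodes:
                    total += d.get("weight", 1.0)
        return total / 2.0
    nbrs = net.neighbor_sets
    return sum(len(nbrs[v] & nodes) for v in nodes) / 2.0


def cluster_stats(net: PPINetwork, cluster: Iterable) -> ClusterStats:
    nodes = set(cluster)
    net.validate_nodes(nodes)
    size = len(nodes)
    w_in = _internal_weight(net, nodes)
    d_mass = float(sum(net.degrees[v] for v in nodes))
    return ClusterStats(
        size=size,
        w_internal=w_in,
        w_boundary=d_mass - 2.0 * w_in,
        max_internal=size * (size - 1) / 2.0,
        degree_mass=d_mass,
    )


def cut_weight(net: PPINetwork, V1: Iterable, V2: Iterable) -> float:
    """W(V1, V2): total weight of edges with one endpoint in each set."""
    s1, s2 = set(V1), set(V2)
    net.validate_nodes(s1 | s2)
    total = 0.0
    for u, v, d in net.graph.subgraph(s1 | s2).edges(data=True):
        if (u in s1 and v in s2) or (v in s1 and u in s2):
            total += d.get("weight", 1.0)
    return total


def _two_way(net: PPINetwork, V1: Iterable, V2: Iterable, kind: str) -> float:
    s1, s2 = set(V1), set(V2)
    if not s1 or not s2:
        raise ValueError("both sides of a bipartition must be non-empty")
    if s1 & s2:
        raise ValueError("two-way objectives require disjoint sides")
    net.validate_nodes(s1 | s2)
    w12 = cut_weight(net, s1, s2)
    if w12 == 0:
        return 0.0
    if kind == "ratio":
        denoms = (len(s1), len(s2))
    else:
        w11 = _internal_weight(net, s1)
        w22 = _internal_weight(net, s2)
        if kind == "minmax":
            denoms = (w11, w22)
        else:  # normalized; degree mass within the scored subgraph V1|V2
            denoms = (2.0 * w11 + w12, 2.0 * w22 + w12)
    if any(d == 0 for d in denoms):
        logger.warning("%s cut: zero denominator; returning +inf sentinel", kind)
        return math.inf
    return w12 / denoms[0] + w12 / denoms[1]


def minmax_cut(net: PPINetwork, V1: Iterable, V2: Iterable) -> float:
    """JM = W12/W11 + W12/W22 (lower is better)."""
    return _two_way(net, V1, V2, "minmax")


def ratio_cut(net: PPINetwork, V1: Iterable, V2: Iterable) -> float:
    """JR = W12/|V1| + W12/|V2| (lower is better)."""
    return _two_way(net, V1, V2, "ratio")


def normalized_cut(net: PPINetwork, V1: Iterable, V2: Iterable) -> float:
    """JN = W12/d1 + W12/d2 with subgraph degree masses (lower is better)."""
    return _two_way(net, V1, V2, "normalized")


def density_fitness(net: PPINetwork, clustering) -> float:
    """JD: sum over clusters of W_kk / (A_k + W_ki); higher is better.

    Singleton and empty clusters contribute 0 (their denominator can be
    0; the degenerate term is defined as 0 rather than raising).
    """
    total = 0.0
    for cluster in _clusters_of(clustering):
        st = cluster_stats(net, cluster)
        denom = st.max_internal + st.w_boundary
        if denom > 0:
            total += st.w_internal / denom
    return total


def multiway_cut_fitness(net: PPINetwork, clustering, kind: str) -> float:
    """k-cluster generalization of a two-way cut objective, negated.

    Sum over clusters of W_ki / D_k with D_k = W_kk (minmax), |C_k|
    (ratio) or d_k with whole-network degrees (normalized).  Terms with
    a zero denominator contribute 0.  The sum is negated so that, like
    JD, higher values are better and one convention drives the GA.
    """
    if kind not in ("minmax", "ratio", "normalized"):
        raise ValueError(f"unknown multiway objective {kind!r}")
    total = 0.0
    for cluster in _clusters_of(clustering):
        st = cluster_stats(net, cluster)
        if kind == "minmax":
            denom = st.w_internal
        elif kind == "ratio":
            denom = st.size
        else:
            denom = st.degree_mass
        if denom > 0:
            total += st.w_boundary / denom
    return -total


def get_objective(name: str) -> Callable[[PPINetwork, object], float]:
    """Resolve an objective name to a maximization fitness callable."""
    if name == "density":
        return density_fitness
    if name in ("minmax", "ratio", "normalized"):
        return lambda net, clustering, _k=name: multiway_cut_fitness(net, clustering, _k)
    raise ValueError(f"unknown objective {name!r}; choose from {OBJECTIVES}")
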