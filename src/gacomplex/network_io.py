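"""Readers, writers and containers for PPI networks, cluster files and complex catalogs.

File dialects are deliberately minimal and text-based:

* edge list — two or three whitespace/tab-delimited columns
  (``proteinA  proteinB  [weight]``), ``#`` comments ignored;
* cluster file — one cluster per line, members tab-separated
  (MCL output compatible);
* reference catalog — one complex per line, complex name followed by
  member protein IDs (MIPS/CYC2008 style).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "ReferenceComplexSet",
    "as_network",
    "read_edge_list",
    "read_clusters",
    "read_reference_complexes",
    "graph_stats",
    "write_clusters",
]


@dataclass
class PPINetwork:
    """An undirected simple graph over named proteins.

    Parameters
    ----------
    graph:
        Simple undirected :class:`networkx.Graph`; no self-loops, edge
        weights (``weight`` attribute) default to 1.0.
    proteins:
        Protein identifiers in a fixed order (order of first appearance
        when read from a file); defines the node index.
    index:
        Bijection protein ID -> position in ``proteins`` (0-based
        internally; documentation and the classic representation count
        nodes 1..N).
    """

    graph: nx.Graph
    proteins: list
    index: dict = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.proteins) != len(set(self.proteins)):
            raise ValueError("duplicate protein identifiers")
        if set(self.proteins) != set(self.graph.nodes):
            raise ValueError("protein list and graph nodes disagree")
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not permitted")
        if self.index != {p: i for i, p in enumerate(self.proteins)}:
            raise ValueError("index is not the bijection induced by `proteins`")
        self._neighbor_sets: dict | None = None
        self._degrees: dict | None = None

    # -- constructors -------------------------------------------------

    @classmethod
    def from_networkx(cls, graph: nx.Graph, order: Iterable | None = None) -> "PPINetwork":
        g = nx.Graph(graph)  # drops parallel edges, copies
        g.remove_edges_from(nx.selfloop_edges(g))
        proteins = list(order) if order is not None else list(g.nodes)
        return cls(g, proteins, {p: i for i, p in enumerate(proteins)})

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        nodes: Iterable | None = None,
    ) -> "PPINetwork":
        """Build from ``(u, v)`` or ``(u, v, weight)`` tuples.

        ``nodes``, when given, fixes the protein order and may include
        isolated proteins; otherwise order of first appearance in the
        edge stream is used.
        """
        g = nx.Graph()
        order: list = []
        seen: set = set()

        def _touch(p):
            if p not in seen:
                seen.add(p)
                order.append(p)
                g.add_node(p)

        if nodes is not None:
            for p in nodes:
                _touch(p)
        n_loops = 0
        for e in edges:
            u, v = e[0], e[1]
            w = float(e[2]) if len(e) > 2 else 1.0
            _touch(u)
            _touch(v)
            if u == v:
                n_loops += 1
                continue
            g.add_edge(u, v, weight=w)
        if n_loops:
            logger.warning("dropped %d self-loop(s)", n_loops)
        return cls(g, order, {p: i for i, p in enumerate(order)})

    # -- basic accessors ----------------------------------------------

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def weighted(self) -> bool:
        return any(d.get("weight", 1.0) != 1.0 for _, _, d in self.graph.edges(data=True))

    @property
    def neighbor_sets(self) -> dict:
        """protein -> set of neighbouring proteins (cached)."""
        if self._neighbor_sets is None:
            self._neighbor_sets = {v: set(self.graph.adj[v]) for v in self.proteins}
        return self._neighbor_sets

    @property
    def degrees(self) -> dict:
        """protein -> (weighted) degree in the whole network (cached)."""
        if self._degrees is None:
            w = "weight" if self.weighted else None
            self._degrees = dict(self.graph.degree(weight=w))
        return self._degrees

    def weight(self, u, v) -> float:
        return self.graph.edges[u, v].get("weight", 1.0)

    def validate_nodes(self, nodes: Iterable) -> None:
        unknown = [v for v in nodes if v not in self.index]
        if unknown:
            raise KeyError(f"unknown protein ID(s): {unknown[:5]}")


@dataclass
class ReferenceComplexSet:
    """A catalog of named reference complexes (gold standard)."""

    complexes: dict

    def __post_init__(self) -> None:
        for name, members in self.complexes.items():
            if not members:
                raise ValueError(f"complex {name!r} is empty")
        self.complexes = {n: frozenset(m) for n, m in self.complexes.items()}

    @property
    def universe(self) -> frozenset:
        return frozenset().union(*self.complexes.values()) if self.complexes else frozenset()

    def __len__(self) -> int:
        return len(self.complexes)

    def restricted_to(self, proteins: Iterable) -> Mapping[str, frozenset]:
        """Complexes intersected with a protein universe; empty ones dropped."""
        keep = set(proteins)
        out = {}
        for name, members in self.complexes.items():
            inter = members & keep
            if inter:
                out[name] = frozenset(inter)
        return out


def as_network(X) -> PPINetwork:
    """Coerce ``X`` into a :class:`PPINetwork`.

    Accepts a PPINetwork (returned as-is), a networkx graph, or a square
    symmetric adjacency matrix (dense or sparse; rows become node
    identifiers ``0..n-1``).
    """
    if isinstance(X, PPINetwork):
        return X
    if isinstance(X, nx.Graph):
        return PPINetwork.from_networkx(X)
    if sp.issparse(X):
        A = X.tocoo()
        n = A.shape[0]
        if A.shape[0] != A.shape[1]:
            raise ValueError("adjacency matrix must be square")
        edges = [
            (int(i), int(j), float(w))
            for i, j, w in zip(A.row, A.col, A.data)
            if i < j and w != 0
        ]
        return PPINetwork.from_edges(edges, nodes=range(n))
    A = np.asarray(X)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency matrix must be symmetric")
    n = A.shape[0]
    edges = [
        (i, j, float(A[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if A[i, j] != 0
    ]
    return PPINetwork.from_edges(edges, nodes=range(n))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _data_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path, delimiter: str | None = None) -> PPINetwork:
    """Read a 2-3 column edge list into a deduplicated simple graph.

    Self-loops are dropped (with a logged count); the first appearance
    of a protein fixes its index. ``delimiter=None`` splits on any
    whitespace (so both TSV and space-separated files work).
    """
    edges = []
    any_line = False
    for lineno, line in _data_lines(path):
        any_line = True
        fields = line.split(delimiter) if delimiter else line.split()
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected >=2 fields, got {len(fields)}")
        if len(fields) >= 3:
            try:
                w = float(fields[2])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: bad weight {fields[2]!r}") from err
            edges.append((fields[0], fields[1], w))
        else:
            edges.append((fields[0], fields[1]))
    if not any_line:
        raise ValueError(f"{path}: empty edge-list file")
    return PPINetwork.from_edges(edges)


def read_clusters(path) -> "Clustering":
    """Read a one-cluster-per-line file (MCL dialect) into a Clustering."""
    from .ga import Clustering  # local import: ga depends on this module

    clusters = []
    for _, line in _data_lines(path):
        members = set(line.split())
        if members:
            clusters.append(members)
    if not clusters:
        raise ValueError(f"{path}: no clusters found")
    return Clustering(clusters)


def read_reference_complexes(path) -> ReferenceComplexSet:
    """Read a MIPS-style catalog: ``name member1 member2 ...`` per line."""
    complexes: dict = {}
    for lineno, line in _data_lines(path):
        fields = line.split()
        name, members = fields[0], fields[1:]
        if name in complexes:
            raise ValueError(f"{path}:{lineno}: duplicate complex name {name!r}")
        uniq = set(members)
        if len(uniq) < len(members):
            logger.warning("%s:%d: duplicate members within complex %s", path, lineno, name)
        if not uniq:
            logger.warning("%s:%d: complex %s has no members; skipped", path, lineno, name)
            continue
        complexes[name] = frozenset(uniq)
    return ReferenceComplexSet(complexes)


# ---------------------------------------------------------------------------
# stats and writers
# ---------------------------------------------------------------------------


def graph_stats(net: PPINetwork) -> dict:
    """Basic network statistics: size, average degree and edge density.

    density = E / (N(N-1)/2), the fraction of potential interactions
    that are present; avg_degree = 2E/N.
    """
    n, e = net.n_proteins, net.n_edges
    if n < 2:
        raise ValueError("density is undefined for networks with fewer than 2 proteins")
    return {
        "n_proteins": n,
        "n_edges": e,
        "avg_degree": 2.0 * e / n,
        "density": e / (n * (n - 1) / 2.0),
    }


def _cluster_list(clustering) -> list:
    return list(getattr(clustering, "clusters", clustering))


def write_clusters(clustering, path) -> None:
    """Write clusters one per line, members tab-separated.

    Members are sorted lexicographically and clusters by (descending
    size, then first member), so output is bit-reproducible.
    """
    clusters = _cluster_list(clustering)
    if not clusters:
        raise ValueError("refusing to write an empty clustering")
    rows = []
    n_empty = 0
    for c in clusters:
        members = sorted(str(m) for m in c)
        if not members:
            n_empty += 1
            continue
        rows.append(members)
    if n_empty:
        logger.warning("skipped %d empty cluster(s)", n_empty)
    rows.sort(key=lambda ms: (-len(ms), ms[0]))
    Path(path).write_text("".join("\t".join(ms) + "\n" for ms in rows), encoding="utf-8")
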