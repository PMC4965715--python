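"""Planted-complex benchmark generator.

Produces a PPI-like network with known ground truth: a set of planted
complexes (dense blocks, edge probability ``p_in``), optional pairs of
complexes sharing nodes (planted overlap), optional filler nodes in no
complex, and sparse background edges (``p_out``) between everything
else.  The returned reference catalog is exactly the planted complexes,
so recovery can be scored with :mod:`gacomplex.evaluation` without any
external data.

Edges are independent Bernoulli draws.  Each unordered node pair gets
one uniform variate in a fixed order, compared against its probability,
so at a fixed seed the edge set grows monotonically with ``p_out`` and
regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_io import PPINetwork, ReferenceComplexSet

__all__ = ["PlantedSpec", "generate"]


@dataclass
class PlantedSpec:
    """Study conditions for a planted-complex benchmark.

    Defaults follow the standard recovery setting used throughout the
    test-bench: six complexes of ten proteins, dense inside
    (p_in = 0.8), sparse background (p_out = 0.02), no planted overlap
    and no filler.
    """

    n_complexes: int = 6
    size_range: tuple = (10, 10)
    p_in: float = 0.8
    p_out: float = 0.02
    overlap_pairs: int = 0
    shared_count: int = 2
    n_filler: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if not (1 <= lo <= hi):
            raise ValueError("size_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.n_complexes < 1:
            raise ValueError("need at least one complex")
        if self.overlap_pairs < 0 or self.n_filler < 0:
            raise ValueError("counts must be non-negative")
        if self.overlap_pairs:
            if self.shared_count < 1 or self.shared_count >= lo:
                raise ValueError("shared_count must be in [1, min complex size)")
            if self.overlap_pairs > self.n_complexes - 1:
                raise ValueError("more overlap pairs than adjacent complex pairs")


def generate(spec: PlantedSpec) -> tuple[PPINetwork, ReferenceComplexSet]:
    """Sample a planted-complex network and its ground-truth catalog.

    Complex sizes are uniform in ``size_range``; the first
    ``overlap_pairs`` adjacent complex pairs (1-2, 2-3, ...) share
    ``shared_count`` proteins.  Protein IDs are zero-padded ("P0001")
    so lexicographic and index order agree.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.size_range
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_complexes)]

    n_total = sum(sizes) - spec.overlap_pairs * spec.shared_count + spec.n_filler
    width = max(4, len(str(n_total)))
    proteins = [f"P{i + 1:0{width}d}" for i in range(n_total)]

    complexes: dict[str, set] = {}
    cursor = 0
    prev_members: list = []
    for ci, size in enumerate(sizes):
        members: list = []
        if ci >= 1 and ci <= spec.overlap_pairs:  # pair (ci-1, ci) shares nodes
            members.extend(prev_members[-spec.shared_count:])
        n_new = size - len(members)
        members.extend(proteins[cursor : cursor + n_new])
        cursor += n_new
        complexes[f"CPX{ci + 1:02d}"] = set(members)
        prev_members = members

    intra: set = set()
    idx = {p: i for i, p in enumerate(proteins)}
    for members in complexes.values():
        ids = sorted(idx[m] for m in members)
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                intra.add((ids[a], ids[b]))

    # one uniform variate per unordered pair, in fixed (i, j) order, so
    # edge sets are reproducible and monotone in the probabilities
    edges = []
    for i in range(n_total):
        u = rng.random(n_total - i - 1)
        for off, j in enumerate(range(i + 1, n_total)):
            p = spec.p_in if (i, j) in intra else spec.p_out
            if u[off] < p:
                edges.append((proteins[i], proteins[j]))

    net = PPINetwork.from_edges(edges, nodes=proteins)
    return net, ReferenceComplexSet(dict(complexes))
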