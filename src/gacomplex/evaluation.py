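"""Scoring predicted clusterings against reference complex catalogs.

A predicted cluster C is matched to a reference complex G by the
hypergeometric tail probability of their overlap: with N network
proteins, M of which belong to G, a random cluster of size n shares at
least k proteins with G with probability

    p = P(X >= k),   X ~ Hypergeometric(N, M, n).

Clusters whose best (minimum-p) match stays significant after
Benjamini-Hochberg correction form the matched set; precision, recall
and F-measure are computed per match from the shared-protein sets

    TP = C & G,  FP = C - G,  TN = G - C
    P = |TP| / |C|,  R = |TP| / |G|,  F = 2PR / (P + R)

and aggregated into a Table-style report (cluster-side mean precision,
complex-side mean recall, harmonic-mean F, plus the discard ratio: the
fraction of network proteins in no predicted complex).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .network_io import PPINetwork, ReferenceComplexSet

__all__ = [
    "MatchRecord",
    "EvaluationReport",
    "hypergeom_pvalue",
    "cluster_metrics",
    "match_and_summarize",
    "compare_methods",
]


@dataclass(frozen=True)
class MatchRecord:
    """Best reference match of one predicted cluster."""

    cluster_id: int
    complex_name: str
    overlap: int
    p_value: float
    precision: float
    recall: float
    f_measure: float


@dataclass
class EvaluationReport:
    """Significant matches plus the Table-style aggregate scores."""

    records: list
    aggregate_recall: float
    aggregate_precision: float
    aggregate_f: float
    discard_ratio: float
    n_clusters: int


def hypergeom_pvalue(N: int, M: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, M, n).

    N: universe size (network proteins); M: marked proteins (complex
    members present in the network); n: cluster size; k: overlap.
    """
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= M, n <= N; got N={N}, M={M}, n={n}")
    if not 0 <= k <= min(M, n):
        raise ValueError(f"need 0 <= k <= min(M, n); got k={k}, M={M}, n={n}")
    if k == 0:
        return 1.0
    # survival function at k-1 gives P(X >= k); scipy evaluates the
    # tail stably (log-space internally for extreme parameters)
    p = float(stats.hypergeom.sf(k - 1, N, M, n))
    return min(1.0, max(p, 5e-324))


def cluster_metrics(cluster, complex_) -> tuple[float, float, float]:
    """(precision, recall, F) of a cluster against one reference complex."""
    c, g = set(cluster), set(complex_)
    if not c or not g:
        raise ValueError("cluster and complex must be non-empty")
    tp = len(c & g)
    precision = tp / len(c)
    recall = tp / len(g)
    f = 0.0 if tp == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f


def _clusters_of(predicted) -> list:
    return [set(c) for c in getattr(predicted, "clusters", predicted)]


def match_and_summarize(
    predicted,
    reference: ReferenceComplexSet,
    net: PPINetwork,
    alpha: float = 0.05,
    bh_correction: bool = True,
) -> EvaluationReport:
    """Match clusters to complexes and aggregate the quality scores.

    For every (cluster, complex) pair with a non-empty overlap the
    hypergeometric p-value is computed with N = network size,
    M = |complex & network|, n = cluster size, k = overlap.  Each
    cluster keeps its minimum-p complex (ties: larger overlap, then
    complex name); those best matches are BH-corrected and kept at
    level ``alpha``.  Aggregate precision averages P over matched
    clusters; aggregate recall averages, over reference complexes with
    at least one network member, the best R any matched cluster
    achieves (0 for complexes nobody found).
    """
    clusters = [c for c in _clusters_of(predicted) if c]
    if not clusters:
        raise ValueError("predicted clustering is empty")
    restricted = reference.restricted_to(net.proteins)
    if not restricted:
        raise ValueError(
            "no reference complex shares any protein with the network; "
            "are the identifier namespaces compatible?"
        )
    N = net.n_proteins

    best: list[tuple[int, str, int, float]] = []  # (cluster_id, name, overlap, p)
    for ci, cluster in enumerate(clusters):
        candidates = []
        for name in sorted(restricted):
            members = restricted[name]
            k = len(cluster & members)
            if k == 0:
                continue
            p = hypergeom_pvalue(N, len(members), len(cluster), k)
            candidates.append((p, -k, name))
        if candidates:
            p, neg_k, name = min(candidates)
            best.append((ci, name, -neg_k, p))

    if best and bh_correction:
        adjusted = stats.false_discovery_control([b[3] for b in best])
    else:
        adjusted = [b[3] for b in best]

    records = []
    for (ci, name, k, p), p_adj in zip(best, adjusted):
        if p_adj <= alpha:
            precision, recall, f = cluster_metrics(clusters[ci], restricted[name])
            records.append(MatchRecord(ci, name, k, p, precision, recall, f))

    if records:
        aggregate_precision = sum(r.precision for r in records) / len(records)
        matched_ids = {r.cluster_id for r in records}
        per_complex = []
        for name in sorted(restricted):
            members = restricted[name]
            best_r = 0.0
            for ci in matched_ids:
                r = len(clusters[ci] & members) / len(members)
                best_r = max(best_r, r)
            per_complex.append(best_r)
        aggregate_recall = sum(per_complex) / len(per_complex)
    else:
        aggregate_precision = 0.0
        aggregate_recall = 0.0
    if aggregate_precision + aggregate_recall > 0:
        aggregate_f = (
            2 * aggregate_precision * aggregate_recall
            / (aggregate_precision + aggregate_recall)
        )
    else:
        aggregate_f = 0.0

    covered = set().union(*clusters)
    discard_ratio = 1.0 - len(covered & set(net.proteins)) / N
    return EvaluationReport(
        records=records,
        aggregate_recall=aggregate_recall,
        aggregate_precision=aggregate_precision,
        aggregate_f=aggregate_f,
        discard_ratio=discard_ratio,
        n_clusters=len(clusters),
    )


def compare_methods(reports) -> pd.DataFrame:
    """Comparison table across methods.

    ``reports`` is a list of ``(method_name, report)`` or
    ``(method_name, {reference_name: report})`` pairs; the result has
    one row per method with #Cls, per-reference R/P/F and the discard
    percentage, rows in input order.
    """
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for name, rep in reports:
        by_ref = rep if isinstance(rep, dict) else {"reference": rep}
        first = next(iter(by_ref.values()))
        row = {"method": name, "n_clusters": first.n_clusters}
        for ref_name, r in by_ref.items():
            row[f"{ref_name}_recall"] = round(r.aggregate_recall, 4)
            row[f"{ref_name}_precision"] = round(r.aggregate_precision, 4)
            row[f"{ref_name}_f_measure"] = round(r.aggregate_f, 4)
        row["discard_pct"] = round(100.0 * first.discard_ratio, 2)
        rows.append(row)
    return pd.DataFrame(rows)
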