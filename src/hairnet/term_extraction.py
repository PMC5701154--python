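"""Weighted term extraction: semantic labels for gene clusters.

Frequent annotations within a cluster are informative only to the extent
that they are rare across clusters. The weight of annotation a in cluster c
is

    w(a, c) = n(a, c) * ln( N_total / n(a, .) )

where n(a, c) counts the genes of cluster c carrying a, n(a, .) is a's
total count over all clusters and N_total the grand total of all counts —
an inverse-document-frequency down-weighting of ubiquitous annotations.
Annotations present in too many clusters are excluded up front (default:
drop if present in more than 60% of clusters) before weights are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import AnnotationMatrix, ClusterPartition


@dataclass
class ClusterTermCounts:
    """Counts n(a, c) as a terms x clusters DataFrame plus aggregates."""

    counts: pd.DataFrame  # index: term_id, columns: cluster_id, values: n(a,c)

    @property
    def per_term_total(self) -> pd.Series:
        """n(a, .) — each annotation's count summed over clusters."""
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        """N_total — all counts over all annotations and clusters."""
        return int(self.counts.to_numpy().sum())

    @property
    def cluster_presence(self) -> pd.Series:
        """Number of clusters in which each annotation appears at least once."""
        return (self.counts >= 1).sum(axis=1)

    @property
    def n_clusters(self) -> int:
        return self.counts.shape[1]


@dataclass
class TermWeightTable:
    """w(a, c) weights, zero wherever n(a, c) = 0, as terms x clusters."""

    weights: pd.DataFrame
    counts: ClusterTermCounts


def count_terms_by_cluster(
    matrix: AnnotationMatrix, partition: ClusterPartition
) -> ClusterTermCounts:
    """n(a, c) = number of genes of cluster c with a 1 in column a."""
    if set(matrix.genes) != set(partition.assignments):
        raise ValueError("partition does not cover the matrix gene set")
    labels = partition.labels(matrix.genes)
    cluster_ids = sorted(set(labels.tolist()))
    cols = {}
    for c in cluster_ids:
        cols[c] = matrix.values[labels == c].sum(axis=0)
    counts = pd.DataFrame(cols, index=matrix.terms)
    return ClusterTermCounts(counts=counts)


def filter_ubiquitous(
    counts: ClusterTermCounts,
    max_fraction: float = 0.6,
    strict: bool = True,
) -> ClusterTermCounts:
    """Drop annotations that appear in too many clusters.

    With ``strict`` (default) an annotation is retained only if it appears
    in fewer than ``max_fraction`` of the clusters (presence <
    max_fraction * n_clusters) — with 35 clusters this keeps presence
    <= 20. With ``strict=False`` retention is presence <=
    floor(max_fraction * n_clusters), i.e. <= 21 with 35 clusters; the two
    conventions differ by exactly one cluster when the product is an
    integer.
    """
    if not 0 < max_fraction <= 1:
        raise ValueError("max_fraction must be in (0, 1]")
    presence = counts.cluster_presence
    if strict:
        keep = presence < max_fraction * counts.n_clusters
    else:
        keep = presence <= int(np.floor(max_fraction * counts.n_clusters))
    if max_fraction == 1:
        keep = presence <= counts.n_clusters
    return ClusterTermCounts(counts=counts.counts.loc[keep])


def term_weights(counts: ClusterTermCounts) -> TermWeightTable:
    """Evaluate w(a, c) = n(a, c) * ln(N_total / n(a, .)) for all pairs."""
    total = counts.grand_total
    if total <= 0:
        raise ValueError("no annotation counts: N_total must be positive")
    per_term = counts.per_term_total.to_numpy(dtype=float)
    idf = np.log(total / per_term)
    weights = counts.counts.to_numpy(dtype=float) * idf[:, None]
    frame = pd.DataFrame(weights, index=counts.counts.index, columns=counts.counts.columns)
    return TermWeightTable(weights=frame, counts=counts)


def top_terms(weights: TermWeightTable, cluster: int, k: int = 20) -> list[tuple[str, float]]:
    """The k highest-weight annotations of a cluster.

    Descending by weight; ties broken lexicographically by term_id.
    Annotations absent from the cluster (weight 0 via count 0) are never
    reported.
    """
    if cluster not in weights.weights.columns:
        raise KeyError(f"unknown cluster id {cluster}")
    col = weights.weights[cluster]
    present = col[weights.counts.counts[cluster] >= 1]
    ranked = sorted(present.items(), key=lambda item: (-item[1], item[0]))
    return [(term, float(w)) for term, w in ranked[:k]]


def mapped_gene_count(
    matrix: AnnotationMatrix,
    partition: ClusterPartition,
    selected: dict[int, list[str]],
) -> dict[int, int]:
    """Per cluster, the number of member genes carrying >= 1 selected term."""
    term_idx = {t: j for j, t in enumerate(matrix.terms)}
    for c, terms in selected.items():
        unknown = [t for t in terms if t not in term_idx]
        if unknown:
            raise ValueError(f"selected terms not in matrix columns: {unknown}")
    labels = partition.labels(matrix.genes)
    out: dict[int, int] = {}
    for c in sorted(set(labels.tolist())):
        cols = [term_idx[t] for t in selected.get(c, [])]
        rows = matrix.values[labels == c]
        if cols:
            out[c] = int((rows[:, cols].sum(axis=1) >= 1).sum())
        else:
            out[c] = 0
    return out


def cluster_summary(
    matrix: AnnotationMatrix,
    partition: ClusterPartition,
    weights: TermWeightTable,
    top_k: int = 20,
) -> pd.DataFrame:
    """One row per cluster: size, mapped genes, top terms joined by ';'."""
    selected = {c: [t for t, _ in top_terms(weights, c, top_k)] for c in weights.weights.columns}
    mapped = mapped_gene_count(matrix, partition, selected)
    sizes = partition.sizes()
    rows = [
        {
            "cluster_id": c,
            "size": sizes[c],
            "mapped_genes": mapped[c],
            "top_terms": ";".join(selected[c]),
        }
        for c in sorted(selected)
    ]
    return pd.DataFrame(rows)
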