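"""Functional hierarchical clustering of genes on binary annotation profiles.

Genes are represented as rows of a binary gene x annotation incidence
matrix restricted to significantly enriched terms. Pairwise dissimilarity is
the Jaccard distance between annotation-term sets; agglomeration is Ward
variance-minimization applied to those dissimilarities via Lance-Williams
updates (scipy's linkage, the standard tool for this step). Clusters are the
connected subtrees below a height threshold h. PCA and t-SNE embeddings are
provided for visual validation of cluster boundaries only; the partition is
always computed on the raw binary matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score

from .enrichment import AnnotationCatalog, EnrichmentTable


@dataclass
class AnnotationMatrix:
    """Binary gene x annotation incidence matrix.

    ``values[i, j] == 1`` iff gene i is a member of term j. Genes with no
    significant annotation are retained as all-zero rows (they remain
    co-clusterable); every term column has at least one nonzero entry by
    construction, since columns come from enrichment output.
    """

    genes: list[str]
    terms: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.genes), len(self.terms)):
            raise ValueError("matrix shape does not match gene/term labels")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("annotation matrix entries must be binary")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene labels")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate term labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.terms)


@dataclass
class DendrogramModel:
    """Agglomerative merge tree in scipy linkage form.

    ``linkage`` is the (n_genes - 1) x 4 scipy matrix: merged node ids,
    merge height, merged size. ``monotone`` flags whether heights are
    non-decreasing along the merge sequence (Ward on non-Euclidean
    dissimilarities can in principle invert; inversions are flagged, not
    repaired).
    """

    linkage: np.ndarray
    genes: list[str]

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError(f"expected {n - 1} merges for {n} genes")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def monotone(self) -> bool:
        return bool(np.all(np.diff(self.heights) >= -1e-12))

    def leaf_order(self) -> list[int]:
        return hierarchy.leaves_list(self.linkage).tolist()

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.genes[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


@dataclass
class ClusterPartition:
    """Gene -> cluster assignment from a dendrogram cut.

    Cluster ids are contiguous 1..k, assigned by order of first appearance
    along the dendrogram leaf order, so labelings are deterministic.
    """

    assignments: dict[str, int]
    h: float | None = None
    k: int = 0

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignments.values()))
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("cluster ids must be contiguous 1..k")
        self.k = len(ids)

    @property
    def genes(self) -> list[str]:
        return list(self.assignments)

    def members(self, cluster_id: int) -> list[str]:
        return [g for g, c in self.assignments.items() if c == cluster_id]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.assignments.values():
            out[c] = out.get(c, 0) + 1
        return out

    def labels(self, gene_order: list[str] | None = None) -> np.ndarray:
        order = gene_order if gene_order is not None else self.genes
        return np.array([self.assignments[g] for g in order])


@dataclass
class EmbeddingResult:
    """2-D coordinates per gene with the provenance of the reduction."""

    genes: list[str]
    coordinates: np.ndarray
    method: str
    n_components: int
    perplexity: float | None
    seed: int | None
    explained_variance_ratio: np.ndarray | None = None


def build_annotation_matrix(
    genes: list[str],
    table: EnrichmentTable,
    catalog: AnnotationCatalog,
) -> AnnotationMatrix:
    """Incidence matrix over the input gene list and the significant terms.

    Entry (g, t) is 1 iff g belongs to term t's catalog member set. Columns
    are restricted to terms flagged significant in the enrichment table.
    """
    if not genes:
        raise ValueError("gene list is empty")
    sig = table.significant_terms
    if not sig:
        raise ValueError("no significant terms: nothing to build the matrix from")
    values = np.zeros((len(genes), len(sig)), dtype=np.int8)
    gene_idx = {g: i for i, g in enumerate(genes)}
    for j, term_id in enumerate(sig):
        for g in catalog.term(term_id).genes:
            i = gene_idx.get(g)
            if i is not None:
                values[i, j] = 1
    return AnnotationMatrix(genes=list(genes), terms=list(sig), values=values)


def jaccard_distances(matrix: AnnotationMatrix) -> np.ndarray:
    """Condensed pairwise Jaccard distances between gene annotation profiles.

    d(i, j) = 1 - |A_i & A_j| / |A_i | A_j| over the genes' term sets. Two
    all-zero profiles get distance 0 (0/0 -> 0) so unannotated genes stay
    co-clusterable; an empty vs a non-empty profile gets distance 1.
    """
    x = matrix.values.astype(np.float64)
    inter = x @ x.T
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 1.0)
    return squareform(dist, checks=False)


def ward_linkage(distances: np.ndarray, genes: list[str]) -> DendrogramModel:
    """Ward variance-minimization agglomeration on given dissimilarities.

    Applies Lance-Williams Ward updates directly to the supplied distances
    (scipy ``linkage(method="ward")``), exactly as is conventional for
    clustering binary profiles under the Jaccard metric despite Ward's
    Euclidean derivation.
    """
    d = np.asarray(distances, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to cluster")
    Z = hierarchy.linkage(d, method="ward")
    return DendrogramModel(linkage=Z, genes=list(genes))


def _relabel_by_leaf_order(raw: np.ndarray, dendrogram: DendrogramModel) -> dict[str, int]:
    remap: dict[int, int] = {}
    for leaf in dendrogram.leaf_order():
        c = int(raw[leaf])
        if c not in remap:
            remap[c] = len(remap) + 1
    return {g: remap[int(raw[i])] for i, g in enumerate(dendrogram.genes)}


def cut_at_height(dendrogram: DendrogramModel, h: float) -> ClusterPartition:
    """Partition genes into the connected subtrees with merge height <= h."""
    if h < 0:
        raise ValueError("height threshold must be non-negative")
    raw = hierarchy.fcluster(dendrogram.linkage, t=h, criterion="distance")
    return ClusterPartition(assignments=_relabel_by_leaf_order(raw, dendrogram), h=float(h))


def cut_to_k(dendrogram: DendrogramModel, k: int) -> ClusterPartition:
    """Cut yielding exactly k clusters (the flat cut just below the
    (n - k)-th merge), convenience for planted-structure recovery."""
    if not 1 <= k <= len(dendrogram.genes):
        raise ValueError("k out of range")
    raw = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    return ClusterPartition(assignments=_relabel_by_leaf_order(raw, dendrogram), h=None)


def pca_reduce(matrix: AnnotationMatrix, n_components: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA scores plus the explained-variance ratio curve.

    The variance curve is the basis for choosing the component count; a
    request exceeding the matrix rank is truncated with a warning from the
    underlying solver rather than an error.
    """
    limit = min(len(matrix.genes), len(matrix.terms))
    if n_components > limit:
        import warnings

        warnings.warn(
            f"n_components={n_components} exceeds min(genes, terms)={limit}; truncated",
            stacklevel=2,
        )
        n_components = limit
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix.values.astype(float))
    return scores, pca.explained_variance_ratio_


def tsne_embed(
    scores: np.ndarray,
    genes: list[str],
    perplexity: float = 30.0,
    seed: int = 0,
    max_iter: int = 500,
) -> EmbeddingResult:
    """2-D t-SNE of (typically PCA-reduced) scores, reproducible by seed.

    Used for visual cluster-boundary validation only — never as clustering
    input.
    """
    n = scores.shape[0]
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < number of genes ({n})")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=max_iter,
    )
    coords = tsne.fit_transform(np.asarray(scores, dtype=float))
    return EmbeddingResult(
        genes=list(genes),
        coordinates=coords,
        method="tsne",
        n_components=scores.shape[1],
        perplexity=perplexity,
        seed=seed,
    )


def perplexity_sweep(
    scores: np.ndarray,
    genes: list[str],
    perplexities: list[float],
    seed: int = 0,
) -> list[EmbeddingResult]:
    """One t-SNE embedding per requested perplexity (boundary validation)."""
    return [tsne_embed(scores, genes, perplexity=p, seed=seed) for p in perplexities]


def partition_agreement(a: ClusterPartition, b: ClusterPartition) -> float:
    """Adjusted Rand index between two partitions of the same gene set.

    1.0 iff the partitions are identical up to relabeling; ~0 expected for
    independent random partitions.
    """
    if set(a.assignments) != set(b.assignments):
        raise ValueError("partitions cover different gene sets")
    order = sorted(a.assignments)
    return float(adjusted_rand_score(a.labels(order), b.labels(order)))
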