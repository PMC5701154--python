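"""Weighted term extraction: naming clusters by their distinctive terms.

Clusters genes from the synthetic generator, then ranks each cluster's
annotations by w(a,c) = n(a,c) * ln(N_total / n(a,.)) — count within the
cluster, down-weighted by ubiquity across clusters. Because each planted
module owns a private annotation pool, the top-ranked terms of each
recovered cluster should come from the matching module's pool.
"""

from hairnet import (
    build_annotation_matrix,
    cut_to_k,
    enrich_catalog,
    jaccard_distances,
    simulate_annotation_catalog,
    ward_linkage,
)
from hairnet.term_extraction import (
    cluster_summary,
    count_terms_by_cluster,
    filter_ubiquitous,
    term_weights,
    top_terms,
)

genes, catalog, universe, truth = simulate_annotation_catalog(seed=2)
table = enrich_catalog(genes, catalog, universe)
matrix = build_annotation_matrix(genes, table, catalog)
partition = cut_to_k(ward_linkage(jaccard_distances(matrix), matrix.genes), 6)

counts = count_terms_by_cluster(matrix, partition)
counts = filter_ubiquitous(counts, max_fraction=0.6)  # drop near-universal terms
weights = term_weights(counts)

for cluster_id in sorted(weights.weights.columns):
    ranked = top_terms(weights, cluster_id, k=3)
    label = ", ".join(f"{t} (w={w:.1f})" for t, w in ranked)
    print(f"cluster {cluster_id}: {label}")
# Each line shows a cluster's three highest-weight annotations; the M<x>
# prefix of the term ids reveals which planted module the cluster captured.

summary = cluster_summary(matrix, partition, weights, top_k=20)
print(summary[["cluster_id", "size", "mapped_genes"]].to_string(index=False))
# mapped_genes counts members annotated by at least one extracted term;
# it can never exceed the cluster size.
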