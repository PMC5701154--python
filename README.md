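# hairnet

Deriving biological modules from a curated disease-gene list.

When genetic mapping of monogenic disorders has produced hundreds of genes
affecting one organ system — the motivating case is the hair follicle, with
a curated archive of 684 genes — the functional annotations those genes
enrich can be mined for higher-order structure. `hairnet` implements that
analysis as a tested, reusable pipeline for geneticists and computational
biologists:

1. **Annotation enrichment** of the gene list against a background
   universe, with an exact one-sided hypergeometric (Fisher) test or the
   conservative jackknifed variant (the EASE score, which removes one gene
   from the overlap cell of the 2×2 table before computing the tail).
   Raw p < α defines significance; molecularly uninformative annotation
   names ("disease mutation", "polymorphism", "sequence variant") are
   removed.
2. **Functional hierarchical clustering**: a binary gene × annotation
   incidence matrix over the significant terms, pairwise Jaccard
   distances d(i,j) = 1 − |A_i ∩ A_j| / |A_i ∪ A_j|, Ward
   variance-minimization agglomeration, and a dendrogram cut at height *h*
   defining gene clusters (biological modules). PCA (default 100
   components) and seeded t-SNE embeddings are provided as visual
   validation diagnostics only.
3. **Weighted term extraction** to label clusters: annotations appearing
   in ≥ 60% of clusters are excluded, and the rest are ranked per cluster
   by w(a,c) = n(a,c) · ln(N_total / n(a,·)) — frequency within the
   cluster, down-weighted by ubiquity across clusters.
4. **Signaling-network analysis**: significant pathways whose names
   contain "signaling" define a bipartite gene–pathway membership graph.
   Hub genes exceed the 95th percentile of pathway degree; pathways
   without hubs are "uncovered", and bridge genes tie them back into the
   network. Louvain community detection runs on the weighted one-mode gene
   projection (edge weight = shared pathway count), with modularity
   Q = Σ_c (w_c/W − (s_c/2W)²) recomputed from the final partition.
5. **Synthetic benchmarks** with planted modules, hubs and bridges, so
   every stage is testable end to end without external downloads, plus
   recovery metrics (adjusted Rand index, hub precision/recall, bridge
   recall).

## Worked example

```python
from hairnet import (
    simulate_annotation_catalog, enrich_catalog, build_annotation_matrix,
    jaccard_distances, ward_linkage, cut_to_k, recovery_report,
)

genes, catalog, universe, truth = simulate_annotation_catalog(seed=1)
table = enrich_catalog(genes, catalog, universe, method="ease", alpha=0.05)
matrix = build_annotation_matrix(genes, table, catalog)
dendrogram = ward_linkage(jaccard_distances(matrix), matrix.genes)
partition = cut_to_k(dendrogram, 6)
print(recovery_report(truth, partition=partition)["module_ari"])
```

This generates 240 genes in 6 planted modules (each module's private
annotations carried with probability 0.6 inside vs 0.02 outside), finds
180 significant terms at α = 0.05, clusters the binary matrix and recovers
the planted modules exactly:

```
240 query genes, 180 annotation terms, universe of 480
180 significant terms at alpha=0.05
cut to k=6 clusters: ARI vs planted modules = 1.000
```

An ARI of 1.0 means the Jaccard–Ward partition matches the planted module
labels up to relabeling. The exact-test core on the hand-checked instance
(overlap 3 of a 4-gene term in a 5-gene query, 20-gene universe) gives

```
hypergeometric tail P(X >= 3) = 0.031992
EASE (jackknifed Fisher)      = 0.097007
```

— the EASE score is the more conservative of the two, by construction.
The `examples/` directory holds one narrative script per capability
(enrichment, clustering, labeling, network analysis, full pipeline); each
prints the numbers above or their network analogues with a comment on
what they mean.

## Command line

```bash
hairnet simulate --out-dir data --seed 1
hairnet all --gene-list data/genes.txt --catalog data/catalog.gmt \
            --universe data/universe.txt --out-dir results --h 1.15
```

`hairnet all` writes the enrichment table, binary matrix, merge table and
Newick dendrogram, cluster assignments, per-cluster term labels, SIF
network export, gene-projection edge list, community assignments, a
network summary JSON and a checksummed manifest. Individual stages are
available as `enrich`, `cluster`, `label` and `network`, so external
enrichment outputs can enter mid-pipeline.

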