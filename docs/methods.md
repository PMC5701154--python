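# Methods

This note documents the models, statistics and design choices behind
`hairnet`, in the order the pipeline runs them.

## Enrichment statistics

A query list of n genes is tested against each annotation term (K member
genes) inside a background universe of N genes. The p-value is the upper
tail P(X ≥ k) of the hypergeometric distribution for the observed overlap
k, evaluated exactly: point masses C(K,i)·C(N−K,n−i)/C(N,n) are summed as
integer ratios (Python big integers) with a single final float division,
so results carry no cancellation error and are stable for N up to ~50,000.

The default statistic is the **EASE score**, the jackknifed Fisher variant
popularized by web-based annotation tools: one gene is removed from the
list∩term cell of the 2×2 table, the other cells are untouched and the
margins are recomputed from the cells, giving P(X ≥ k−1) under
Hypergeometric(N−1, K−1, n−1). The jackknife penalizes terms supported by
a single overlapping gene (k = 1 always scores 1.0) and is never smaller
than the plain tail. The plain hypergeometric test is selectable.

Significance is the raw rule p < α (default α = 0.05) with **no
multiple-testing correction**, matching the screening convention of
annotation tools this stage replaces; a Benjamini–Hochberg column is
emitted for information only. Terms with zero overlap are suppressed.
Annotation names that flag disease association without molecular content
("disease mutation", "polymorphism", "sequence variant") are removed by a
configurable exact-match blocklist.

Gene identifiers are normalized by uppercasing and whitespace stripping
only; alias resolution is assumed to have happened upstream during
curation to standard (HGNC-style) symbols.

## Binary matrix, Jaccard distance, Ward clustering

The cluster analysis operates on the binary gene × annotation incidence
matrix restricted to significant terms. Distance between genes is the
Jaccard distance of their term sets. Two conventions are fixed
deliberately: two all-zero profiles have distance 0 (unannotated genes
remain co-clusterable rather than undefined), and an empty vs a non-empty
profile has distance 1. Genes with no significant annotation are retained
as all-zero rows.

Agglomeration is Ward variance minimization applied directly to the
Jaccard dissimilarities through the Lance–Williams update

d(i∪j, k) = √[((n_i+n_k)·d_ik² + (n_j+n_k)·d_jk² − n_k·d_ij²)/(n_i+n_j+n_k)],

via `scipy.cluster.hierarchy.linkage(method="ward")` — the standard tool
call for this analysis. Ward's derivation assumes Euclidean distances;
applying it to Jaccard dissimilarities is a widely used pragmatic choice
and is made here knowingly. When the current minimum merge distance is
tied, the nearest-neighbor-chain algorithm inside scipy resolves the tie
by its own traversal order; tied instances admit several valid
agglomerations, and the test oracle (a naive O(n³) re-implementation of
the same recurrence) therefore refuses tied inputs rather than guessing.
Merge heights are checked for monotonicity and flagged, not repaired, if
an inversion appears.

Clusters are the connected subtrees below a height threshold h (default
1.15, freely settable — the threshold is an empirical knob chosen by
inspecting label quality at several cuts). Cluster ids are assigned
1..k by order of first appearance along the dendrogram leaf order, making
labelings deterministic. A `cut_to_k` convenience cut is provided for
benchmark recovery, where the planted module count is known.

PCA (default 100 components, with the explained-variance curve reported
for choosing the count; requests beyond the matrix rank are truncated with
a warning) and seeded t-SNE (perplexity must be below the gene count;
default 500 optimizer iterations) are **diagnostics only**: the partition
is always computed on the raw binary matrix, and a test asserts it is
invariant to whether embeddings are run.

## Cluster labeling by weighted term extraction

For cluster c and annotation a, n(a,c) is the number of cluster-c genes
carrying a (the binary-matrix column sum within the cluster — the only
counting unit the pipeline possesses). With n(a,·) the total over clusters
and N_total the grand total, the weight is

w(a,c) = n(a,c) · ln(N_total / n(a,·)),

an inverse-document-frequency down-weighting of ubiquitous annotations:
an annotation carrying all incidences has weight 0 everywhere, as does any
(a,c) with n(a,c) = 0.

Before weighting, annotations appearing in too many clusters are dropped.
The default rule retains an annotation only if it appears in fewer than
60% of the clusters (presence < 0.6·k); with 35 clusters this retains
presence ≤ 20. An alternative convention (presence ≤ floor(0.6·k), i.e.
≤ 21 with 35 clusters) differs by exactly one cluster when 0.6·k is an
integer and is available behind a flag, since both phrasings circulate.
Filtering happens before weights are computed, so N_total excludes the
dropped annotations; the filter-after-weighting alternative would change
only the constant inside the logarithm.

Per cluster, the top-k terms (default 20) are ranked by descending weight
with lexicographic tie-breaking, and the "mapped genes" statistic counts
member genes carrying at least one extracted term (never exceeding the
cluster size). A packaged reference table of the published 35-cluster
summary (sizes and mapped counts, totalling 684 genes) backs the
consistency checks.

## Signaling network

Significant terms whose names contain the substring "signaling"
(case-insensitive) are taken as cellular signaling pathways. The bipartite
membership graph links gene g to pathway p iff g is in p's member set and
in the analysis gene list; pathways left without members and genes in no
selected pathway are excluded, so the graph has no isolated nodes.

**Hubs** are genes whose pathway degree strictly exceeds the 95th
percentile of the gene degree distribution, computed with linear
interpolation between order statistics (so with degrees 1..10 the 90th
percentile is 9.1). Strict inequality reproduces the "more than t
pathways" reading of an empirical percentile threshold. **Uncovered**
pathways contain no hub; a **bridge gene** belongs to at least one
uncovered pathway and at least two pathways overall, tying the uncovered
pathway into the remainder of the network — uncovered pathways whose
members all have degree 1 are reported isolated.

Community detection runs on the weighted one-mode gene projection (edge
weight = number of shared pathways) — the standard reading of "communities
of genes with similar pathway membership"; the raw bipartite adjacency can
be substituted where wanted. Louvain greedy modularity optimization is
node-order sensitive, so the seed is explicit and a best-of-R restart
option exists; the reported Q is always recomputed from the final
partition with the package's own Newman–Girvan implementation
Q = Σ_c (w_c/W − (s_c/2W)²), which an independent double-sum oracle and
networkx's modularity both confirm in tests. An edgeless graph yields
singleton communities with Q = 0.

## Synthetic benchmarks

`simulate_annotation_catalog` plants M = 6 modules of 40 genes (240 query
genes). Each module owns 30 private annotation terms; a module gene
carries each with probability p_in = 0.6, every other gene — including a
background universe of 240 further genes (universe = 2× the query) — with
p_out = 0.02. Background genes carrying annotations at p_out makes the
query's enrichment detectable by construction, so the stages compose
without hand-tuned fixtures. A fifth of each module's terms are named as
signaling pathways so the network stage has input in full-pipeline runs.
Terms left with no carrier are dropped (they are untestable).

`simulate_pathway_membership` plants 200 genes × 40 pathways with 10 hub
genes joining each covered pathway at rate 0.6 against a 0.05 background.
Three designated uncovered pathways exclude hubs by construction and each
receives two designated bridge genes that are also forced into a covered
pathway. Every gene is guaranteed at least one membership — a gene–pathway
membership table has no degree-0 gene rows by definition — and every
pathway at least one member. A single integer seed drives each generator
call through one numpy Generator stream; repeated calls are byte-identical
on disk.

What the generators do **not** emulate: real GO/KEGG term hierarchies and
their correlation structure, term-size distributions, gene-symbol
semantics, overlapping module membership, or annotation noise that is
correlated across terms. Passing recovery tests therefore demonstrate
that the pipeline's machinery is correct and composable, not that real
curated datasets will cluster as cleanly.

Recovery is scored by the adjusted Rand index against planted module
labels, hub precision/recall against planted hubs, and bridge recall. At
the benchmark conditions the clustering chain attains ARI ≥ 0.9 in at
least 95% of 50 seeded replicates and hub recall ≥ 0.9 (both observed at
1.0), and a 2,000-replicate null simulation keeps the fraction of p < 0.05
calls at the nominal level (≤ 0.07 allowing sampling error).

## Numerical and interface choices

- Exact tests: integer arithmetic until the final division; inconsistent
  count tuples (k > K, n > N, ...) raise naming the violated inequality.
- Percentiles: numpy's linear interpolation, the field's default.
- Degenerate inputs: empty query after universe intersection, empty
  catalog, zero significant terms, NaN distances, perplexity ≥ n, and
  alpha outside (0,1] all raise before computation.
- Pipeline runs are deterministic given the configured seeds; the output
  manifest records a sha256 per artifact, and a test asserts two runs of
  the same config produce identical checksums.
- Problem sizes in the test suite and acceptance script (50 generator
  replicates for each recovery chain, 2,000 null replicates, exhaustive
  oracles at n ≤ 25 margins and 8-node partition enumeration) were chosen
  as the smallest sizes at which the checks are statistically meaningful;
  they complete in seconds on one CPU.

## Known limitations

- Reproducing a published enrichment count from a live annotation service
  is inherently version-dependent; this package fixes the statistics, not
  the annotation content. Analyses of real curated archives require the
  corresponding catalog and universe as inputs.
- Ward-on-Jaccard has no variance interpretation; it is provided for
  fidelity to the established workflow, with the caveat documented above.
- The ubiquity filter and term weights treat annotations as atomic ids;
  no linguistic processing of annotation names is attempted, and composing
  prose cluster descriptions from the ranked terms is left to the analyst.
- Louvain is a greedy heuristic: different seeds can return different
  partitions with slightly different Q; use restarts and report the seed.
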