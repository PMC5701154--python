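"""hairnet: biological-module derivation from curated disease-gene lists.

Pipeline stages, each an importable module:

* :mod:`hairnet.enrichment` — hypergeometric / EASE annotation enrichment
* :mod:`hairnet.clustering` — binary annotation matrix, Jaccard distances,
  Ward agglomeration, height-cut partitions, PCA/t-SNE diagnostics
* :mod:`hairnet.term_extraction` — weighted (TF-IDF-style) cluster labels
* :mod:`hairnet.signaling_network` — bipartite gene-pathway network, hub
  and bridge detection, Louvain communities with modularity
* :mod:`hairnet.synthetic` — planted-structure benchmark generators
* :mod:`hairnet.io` / :mod:`hairnet.pipeline` / :mod:`hairnet.cli` —
  formats, orchestration, command line
"""

from importlib.resources import files as _files

__version__ = "0.1.0"

from .enrichment import (  # noqa: F401
    AnnotationCatalog,
    AnnotationTerm,
    EnrichmentTable,
    GeneUniverse,
    ease_score,
    enrich_catalog,
    filter_uninformative,
    hypergeometric_tail,
)
from .clustering import (  # noqa: F401
    AnnotationMatrix,
    ClusterPartition,
    DendrogramModel,
    build_annotation_matrix,
    cut_at_height,
    cut_to_k,
    jaccard_distances,
    partition_agreement,
    pca_reduce,
    tsne_embed,
    ward_linkage,
)
from .term_extraction import (  # noqa: F401
    count_terms_by_cluster,
    filter_ubiquitous,
    term_weights,
    top_terms,
)
from .signaling_network import (  # noqa: F401
    BipartiteNetwork,
    CommunityResult,
    build_bipartite,
    bridge_genes,
    degree_table,
    hub_threshold,
    louvain_communities,
    modularity,
    project_genes,
    select_signaling_pathways,
    uncovered_pathways,
)
from .synthetic import (  # noqa: F401
    ModuleParams,
    PathwayParams,
    SyntheticTruth,
    recovery_report,
    simulate_annotation_catalog,
    simulate_pathway_membership,
)
from .pipeline import PipelineConfig, run_pipeline  # noqa: F401


def reference_cluster_table():
    """The published per-cluster summary (35 clusters: size, mapped genes).

    Returned as a DataFrame read from the packaged text fixture; used for
    consistency checks (sizes sum to the 684-gene archive; mapped genes
    never exceed cluster size).
    """
    import pandas as pd

    path = _files("hairnet").joinpath("data/reference_clusters.tsv")
    return pd.read_csv(str(path), sep="\t")
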