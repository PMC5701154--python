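"""End-to-end pipeline orchestration.

Runs enrichment -> uninformative-term filter -> binary matrix -> Jaccard
distances -> Ward linkage -> height cut -> weighted term extraction ->
signaling network -> Louvain communities, writing every artifact to the
configured output directory and finishing with a checksummed manifest. All
free parameters of the analysis live on :class:`PipelineConfig`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import clustering, enrichment, io, signaling_network, term_extraction

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and free parameters of a pipeline run.

    ``h`` (dendrogram cut height), ``alpha`` (raw enrichment significance),
    ``percentile`` (hub degree percentile), ``max_fraction`` (term
    ubiquity cut) and ``top_k`` (labels per cluster) are the analysis'
    tunable knobs.
    """

    gene_list: str = ""
    catalog: str = ""
    universe: str = ""
    out_dir: str = "hairnet_out"
    alpha: float = 0.05
    method: str = "ease"
    blocklist: list[str] = field(default_factory=lambda: list(enrichment.DEFAULT_BLOCKLIST))
    h: float = 1.15
    percentile: float = 95.0
    max_fraction: float = 0.6
    strict_ubiquity: bool = True
    top_k: int = 20
    louvain_seed: int = 0
    louvain_restarts: int = 1
    signaling_keyword: str = "signaling"

    def validate(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0 < self.max_fraction <= 1:
            raise ValueError(f"max_fraction must be in (0, 1], got {self.max_fraction}")
        if self.h < 0:
            raise ValueError("h must be >= 0")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.method not in ("ease", "hypergeometric"):
            raise ValueError(f"unknown enrichment method {self.method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return the artifact manifest.

    Every stage logs its parameters; any stage error raises
    :class:`StageError` naming the stage, leaving earlier artifacts on
    disk. Deterministic given the configured seeds.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    io.write_json(config.to_dict(), out / "config.json")
    artifacts["config"] = out / "config.json"

    def stage(name):
        logger.info("stage %s", name)
        return name

    try:
        name = stage("load")
        genes = io.read_gene_list(config.gene_list)
        universe = io.read_universe(config.universe)
        catalog = io.read_gmt(config.catalog, universe)

        name = stage("enrich")
        logger.info("enrich: method=%s alpha=%s", config.method, config.alpha)
        table = enrichment.enrich_catalog(
            genes, catalog, universe, method=config.method, alpha=config.alpha
        )
        table = enrichment.filter_uninformative(table, config.blocklist)
        io.write_enrichment(table, out / "enrichment.tsv")
        artifacts["enrichment"] = out / "enrichment.tsv"

        name = stage("matrix")
        matrix = clustering.build_annotation_matrix(genes, table, catalog)
        io.write_matrix(matrix, out / "matrix.tsv")
        artifacts["matrix"] = out / "matrix.tsv"

        name = stage("cluster")
        logger.info("cluster: h=%s", config.h)
        distances = clustering.jaccard_distances(matrix)
        dendrogram = clustering.ward_linkage(distances, matrix.genes)
        io.write_dendrogram(dendrogram, out / "merges.tsv", out / "dendrogram.nwk")
        artifacts["merges"] = out / "merges.tsv"
        artifacts["newick"] = out / "dendrogram.nwk"
        partition = clustering.cut_at_height(dendrogram, config.h)
        io.write_partition(partition, out / "clusters.tsv")
        artifacts["clusters"] = out / "clusters.tsv"

        name = stage("label")
        counts = term_extraction.count_terms_by_cluster(matrix, partition)
        counts = term_extraction.filter_ubiquitous(
            counts, config.max_fraction, strict=config.strict_ubiquity
        )
        weights = term_extraction.term_weights(counts)
        rows = []
        for c in weights.weights.columns:
            for rank, (term, w) in enumerate(
                term_extraction.top_terms(weights, c, config.top_k), start=1
            ):
                rows.append(
                    {
                        "cluster_id": c,
                        "rank": rank,
                        "term_id": term,
                        "category": catalog.term(term).category,
                        "weight": w,
                        "n_in_cluster": int(counts.counts.loc[term, c]),
                    }
                )
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "cluster_terms.tsv", sep="\t", index=False)
        artifacts["cluster_terms"] = out / "cluster_terms.tsv"
        summary = term_extraction.cluster_summary(matrix, partition, weights, config.top_k)
        summary.to_csv(out / "cluster_summary.tsv", sep="\t", index=False)
        artifacts["cluster_summary"] = out / "cluster_summary.tsv"

        name = stage("network")
        logger.info("network: percentile=%s keyword=%s", config.percentile, config.signaling_keyword)
        pathways = signaling_network.select_signaling_pathways(table, config.signaling_keyword)
        net = signaling_network.build_bipartite(pathways, catalog, genes)
        degrees = signaling_network.degree_table(net, config.percentile)
        projection = signaling_network.project_genes(net)
        communities = signaling_network.louvain_communities(
            projection, seed=config.louvain_seed, restarts=config.louvain_restarts
        )
        io.write_sif(net, out / "network.sif")
        io.write_edge_list(projection, out / "gene_projection.tsv")
        io.write_communities(communities, out / "communities.tsv")
        net_summary = signaling_network.network_summary(net, degrees, communities)
        io.write_json(net_summary, out / "network_summary.json")
        artifacts["network_sif"] = out / "network.sif"
        artifacts["gene_projection"] = out / "gene_projection.tsv"
        artifacts["communities"] = out / "communities.tsv"
        artifacts["network_summary"] = out / "network_summary.json"
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, exc) from exc

    manifest = io.write_manifest(artifacts, out / "manifest.json")
    return manifest
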