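"""Readers and writers for the pipeline's plain-text formats.

Formats: gene lists (one symbol per line), GMT and long-form TSV annotation
catalogs, TSV tables (enrichment, matrix, partition, merges, communities),
SIF and edge-list network exports, Newick dendrograms, and JSON summaries.
All gene symbols are normalized (uppercased, stripped) on read; all TSVs
carry headers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import AnnotationMatrix, ClusterPartition, DendrogramModel
from .enrichment import AnnotationCatalog, AnnotationTerm, EnrichmentTable, GeneUniverse, normalize_symbol
from .signaling_network import BipartiteNetwork, CommunityResult

logger = logging.getLogger(__name__)


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line (first TSV column if tabbed); deduplicated with
    a warning, order of first appearance preserved."""
    path = Path(path)
    genes: list[str] = []
    seen: set[str] = set()
    dupes = 0
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"empty gene list file: {path}")
    for line in text.splitlines():
        raw = line.split("\t")[0]
        g = normalize_symbol(raw)
        if not g or g.startswith("#"):
            continue
        if g in seen:
            dupes += 1
            continue
        seen.add(g)
        genes.append(g)
    if dupes:
        logger.warning("%d duplicate gene symbol(s) dropped from %s", dupes, path)
    return genes


def read_universe(path: str | Path) -> GeneUniverse:
    return GeneUniverse.from_iterable(read_gene_list(path))


def read_gmt(path: str | Path, universe: GeneUniverse) -> AnnotationCatalog:
    """GMT: term_id <tab> category/description <tab> gene1 <tab> gene2 ..."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"empty GMT file: {path}")
    terms = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
        term_id, category, *genes = fields
        terms.append(
            AnnotationTerm(term_id, category, frozenset(normalize_symbol(g) for g in genes if g))
        )
    return AnnotationCatalog(terms=terms, universe=universe)


def read_catalog_tsv(path: str | Path, universe: GeneUniverse) -> AnnotationCatalog:
    """Long-form catalog TSV with header (term_id, category, gene)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"term_id", "category", "gene"}
    if not needed <= set(frame.columns):
        raise ValueError(f"catalog TSV must have columns {sorted(needed)}")
    terms = []
    for (term_id, category), grp in frame.groupby(["term_id", "category"], sort=False):
        terms.append(
            AnnotationTerm(term_id, category, frozenset(normalize_symbol(g) for g in grp["gene"]))
        )
    return AnnotationCatalog(terms=terms, universe=universe)


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def write_gmt(catalog: AnnotationCatalog, path: str | Path) -> None:
    lines = [
        "\t".join([t.term_id, t.category, *sorted(t.genes)])
        for t in catalog
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_enrichment(table: EnrichmentTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_enrichment(path: str | Path, alpha: float = 0.05, method: str = "ease") -> EnrichmentTable:
    frame = pd.read_csv(path, sep="\t")
    return EnrichmentTable(frame=frame, alpha=alpha, method=method)


def write_matrix(matrix: AnnotationMatrix, path: str | Path) -> None:
    """Gene rows, term columns; first column 'gene'."""
    frame = matrix.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> AnnotationMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return AnnotationMatrix(
        genes=[normalize_symbol(g) for g in frame.index],
        terms=list(frame.columns),
        values=frame.to_numpy(dtype=np.int8),
    )


def write_partition(partition: ClusterPartition, path: str | Path) -> None:
    frame = pd.DataFrame(
        {"gene": list(partition.assignments), "cluster_id": list(partition.assignments.values())}
    )
    frame.to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path) -> ClusterPartition:
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str, "cluster_id": int})
    return ClusterPartition(
        assignments={normalize_symbol(g): int(c) for g, c in zip(frame["gene"], frame["cluster_id"])}
    )


def write_dendrogram(dendrogram: DendrogramModel, merges_path: str | Path, newick_path: str | Path) -> None:
    """Merge table TSV (left, right, height, size) plus a Newick export."""
    frame = pd.DataFrame(dendrogram.linkage, columns=["left", "right", "height", "size"])
    frame[["left", "right", "size"]] = frame[["left", "right", "size"]].astype(int)
    frame.to_csv(merges_path, sep="\t", index=False)
    Path(newick_path).write_text(dendrogram.to_newick() + "\n")


def write_sif(net: BipartiteNetwork, path: str | Path) -> None:
    """SIF export: gene <tab> member_of <tab> pathway."""
    lines = []
    for g in net.genes:
        for p in sorted(net.graph.neighbors(g)):
            lines.append(f"{g}\tmember_of\t{p}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_edge_list(graph, path: str | Path) -> None:
    """Weighted gene-projection edge list TSV (gene_a, gene_b, weight)."""
    rows = [
        {"gene_a": min(u, v), "gene_b": max(u, v), "weight": d.get("weight", 1)}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).sort_values(
        ["gene_a", "gene_b"]
    ).to_csv(path, sep="\t", index=False)


def write_communities(result: CommunityResult, path: str | Path) -> None:
    frame = pd.DataFrame(
        {"gene": list(result.assignments), "community_id": list(result.assignments.values())}
    ).sort_values("gene")
    frame.to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(artifacts: dict[str, Path], path: str | Path) -> dict:
    """Record every artifact written, with a checksum, as JSON."""
    manifest = {
        name: {"path": str(p), "sha256": sha256_of(p)} for name, p in sorted(artifacts.items())
    }
    write_json(manifest, path)
    return manifest
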