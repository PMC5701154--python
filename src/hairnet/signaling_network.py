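"""Bipartite gene-pathway signaling network: hubs, bridges, communities.

Significantly enriched pathways whose names contain "signaling" define a
bipartite membership graph between genes and pathways. Highly connected
(hub) genes are those whose pathway degree exceeds a percentile of the
degree distribution (default the 95th). Pathways containing no hub are
"uncovered"; genes that tie an uncovered pathway into the rest of the
network are bridge genes. Gene communities are found by Louvain modularity
optimization on the weighted one-mode gene projection (edge weight = number
of shared pathways).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_community

from .enrichment import AnnotationCatalog, EnrichmentTable


@dataclass
class BipartiteNetwork:
    """Gene-pathway membership graph (two-colorable by construction)."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v in self.graph.edges():
            if self.graph.nodes[u]["kind"] == self.graph.nodes[v]["kind"]:
                raise ValueError(f"edge {u!r}-{v!r} joins two nodes of the same kind")

    @classmethod
    def from_memberships(cls, memberships: list[tuple[str, str]]) -> "BipartiteNetwork":
        """Build from (gene, pathway) pairs; duplicates collapse to one edge."""
        g = nx.Graph()
        for gene, pathway in memberships:
            g.add_node(gene, kind="gene", bipartite=0)
            g.add_node(pathway, kind="pathway", bipartite=1)
            g.add_edge(gene, pathway)
        return cls(graph=g)

    @property
    def genes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "gene")

    @property
    def pathways(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "pathway")

    def members(self, pathway: str) -> set[str]:
        return set(self.graph.neighbors(pathway))

    def gene_degree(self, gene: str) -> int:
        return self.graph.degree(gene)


@dataclass
class DegreeTable:
    """Per-gene pathway counts with the hub threshold and flags."""

    degrees: pd.Series  # index gene, value pathway count
    threshold: float
    percentile: float

    @property
    def hubs(self) -> set[str]:
        """Genes with degree strictly greater than the threshold."""
        return set(self.degrees[self.degrees > self.threshold].index)


@dataclass
class CommunityResult:
    """Gene -> community map with the recomputed modularity Q."""

    assignments: dict[str, int]
    q: float
    seed: int

    @property
    def n_communities(self) -> int:
        return len(set(self.assignments.values()))


def select_signaling_pathways(table: EnrichmentTable, keyword: str = "signaling") -> list[str]:
    """Significant terms whose name contains the keyword (case-insensitive)."""
    frame = table.frame
    mask = frame["significant"] & frame["term_id"].str.contains(keyword, case=False, regex=False)
    selected = frame.loc[mask, "term_id"].tolist()
    if not selected:
        raise ValueError(
            f"no significant term contains {keyword!r}; "
            "check that pathway-category annotations are present"
        )
    return selected


def build_bipartite(
    pathways: list[str],
    catalog: AnnotationCatalog,
    genes: list[str],
) -> BipartiteNetwork:
    """Membership graph over the selected pathways and the input gene list.

    Edge (g, p) iff g is in p's catalog member set and g is in the input
    list. Genes belonging to no selected pathway do not appear; neither do
    pathways left without members (no isolated pathway nodes).
    """
    gene_set = set(genes)
    memberships = []
    for p in pathways:
        term = catalog.term(p)
        for g in term.genes & gene_set:
            memberships.append((g, p))
    return BipartiteNetwork.from_memberships(memberships)


def degree_table(net: BipartiteNetwork, percentile: float = 95.0) -> DegreeTable:
    """Gene degree distribution with its percentile hub threshold.

    The threshold is the given percentile of gene degrees under linear
    interpolation between order statistics; hubs are genes with degree
    strictly above it.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    genes = net.genes
    if not genes:
        raise ValueError("network has no gene nodes")
    degrees = pd.Series({g: net.gene_degree(g) for g in genes}).sort_values(ascending=False)
    t = hub_threshold(degrees.to_numpy(), percentile)
    return DegreeTable(degrees=degrees, threshold=t, percentile=percentile)


def hub_threshold(degrees: np.ndarray, percentile: float = 95.0) -> float:
    """Percentile of the degree distribution (linear interpolation)."""
    d = np.asarray(degrees, dtype=float)
    if d.size == 0:
        raise ValueError("empty degree distribution")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    return float(np.percentile(d, percentile, method="linear"))


def uncovered_pathways(net: BipartiteNetwork, hubs: set[str]) -> set[str]:
    """Pathways containing no hub gene."""
    unknown = hubs - set(net.genes)
    if unknown:
        raise ValueError(f"hub genes not in network: {sorted(unknown)}")
    return {p for p in net.pathways if not (net.members(p) & hubs)}


def bridge_genes(
    net: BipartiteNetwork, uncovered: set[str]
) -> tuple[set[str], dict[str, bool]]:
    """Genes linking uncovered pathways into the rest of the network.

    A bridge gene belongs to at least one uncovered pathway and to at least
    two pathways in total. Returns the bridge set plus, per uncovered
    pathway, whether it is thereby connected (True) or isolated (False).
    """
    unknown = uncovered - set(net.pathways)
    if unknown:
        raise ValueError(f"uncovered pathways not in network: {sorted(unknown)}")
    bridges: set[str] = set()
    connected: dict[str, bool] = {}
    for p in uncovered:
        p_bridges = {g for g in net.members(p) if net.gene_degree(g) >= 2}
        bridges |= p_bridges
        connected[p] = bool(p_bridges)
    return bridges, connected


def project_genes(net: BipartiteNetwork) -> nx.Graph:
    """Weighted one-mode projection onto genes.

    Edge weight = number of pathways the two genes share; genes sharing no
    pathway are not adjacent. No self-loops.
    """
    g = nx.Graph()
    g.add_nodes_from(net.genes)
    for p in net.pathways:
        members = sorted(net.members(p))
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if g.has_edge(a, b):
                    g[a][b]["weight"] += 1
                else:
                    g.add_edge(a, b, weight=1)
    return g


def modularity(graph: nx.Graph, partition: dict[str, int]) -> float:
    """Weighted Newman-Girvan modularity of a partition.

    Q = sum_c ( w_c / W - (s_c / 2W)^2 ), with W the total edge weight,
    w_c the intra-community weight and s_c the community strength (sum of
    member node strengths).
    """
    missing = set(graph.nodes()) - set(partition)
    if missing:
        raise ValueError(f"nodes missing from partition: {sorted(missing)[:5]}")
    W = graph.size(weight="weight")
    if W == 0:
        return 0.0
    intra: dict[int, float] = {}
    strength: dict[int, float] = {}
    for u, v, w in graph.edges(data="weight", default=1):
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0.0) + w
    for node in graph.nodes():
        c = partition[node]
        strength[c] = strength.get(c, 0.0) + graph.degree(node, weight="weight")
    q = 0.0
    for c in set(partition.values()):
        q += intra.get(c, 0.0) / W - (strength.get(c, 0.0) / (2 * W)) ** 2
    return q


def louvain_communities(
    graph: nx.Graph, seed: int = 0, restarts: int = 1
) -> CommunityResult:
    """Louvain greedy modularity optimization on the gene graph.

    The method is node-order sensitive, so the seed controls the shuffle;
    with ``restarts`` > 1 the best-Q partition over R seeded runs is kept.
    The reported Q is always recomputed from the final partition by
    :func:`modularity`. An edgeless graph yields singleton communities with
    Q = 0.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.number_of_edges() == 0:
        assignments = {n: i + 1 for i, n in enumerate(sorted(graph.nodes()))}
        return CommunityResult(assignments=assignments, q=0.0, seed=seed)
    best: CommunityResult | None = None
    for r in range(max(1, restarts)):
        run_seed = seed + r
        comms = nx_community.louvain_communities(graph, weight="weight", seed=run_seed)
        assignments: dict[str, int] = {}
        for i, comm in enumerate(sorted(comms, key=lambda c: sorted(c)[0])):
            for node in comm:
                assignments[node] = i + 1
        q = modularity(graph, assignments)
        if best is None or q > best.q:
            best = CommunityResult(assignments=assignments, q=q, seed=run_seed)
    return best


def network_summary(
    net: BipartiteNetwork,
    degrees: DegreeTable,
    communities: CommunityResult,
) -> dict:
    """Headline statistics of the signaling-network analysis as a dict."""
    hubs = degrees.hubs
    uncovered = uncovered_pathways(net, hubs)
    bridges, connected = bridge_genes(net, uncovered)
    return {
        "n_genes": len(net.genes),
        "n_pathways": len(net.pathways),
        "percentile": degrees.percentile,
        "hub_threshold": degrees.threshold,
        "n_hubs": len(hubs),
        "hubs": sorted(hubs),
        "n_covered_pathways": len(net.pathways) - len(uncovered),
        "n_uncovered_pathways": len(uncovered),
        "uncovered_pathways": sorted(uncovered),
        "n_bridge_genes": len(bridges),
        "bridge_genes": sorted(bridges),
        "uncovered_connected": connected,
        "modularity": communities.q,
        "n_communities": communities.n_communities,
        "louvain_seed": communities.seed,
    }
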