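"""Synthetic benchmarks with planted structure for every pipeline stage.

Two generators stand in for a curated disease-gene dataset:

* :func:`simulate_annotation_catalog` plants gene modules in a binary
  gene x annotation incidence structure: each module owns a private pool of
  annotation terms that its genes carry with probability ``p_in`` while all
  other genes (including a background universe twice the query size) carry
  them at the much lower rate ``p_out``. Enrichment of the query list is
  detectable by construction, and the planted module labels are the ground
  truth for clustering recovery.

* :func:`simulate_pathway_membership` plants the topology of a signaling
  membership network: hub genes joining most pathways, a block of pathways
  that exclude all hubs ("uncovered"), and designated bridge genes tying
  each uncovered pathway back into the covered part of the network.

A single integer seed drives all draws of a generator call through one
numpy Generator stream, so outputs are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .clustering import ClusterPartition
from .enrichment import AnnotationCatalog, AnnotationTerm, GeneUniverse
from .signaling_network import BipartiteNetwork, CommunityResult


@dataclass(frozen=True)
class ModuleParams:
    """Planted-module generator settings.

    Defaults describe a moderately hard recovery problem: 6 modules of 40
    genes, 30 private annotations per module, within-module carry
    probability 0.6 against a 0.02 background, over a universe twice the
    query size.
    """

    n_modules: int = 6
    genes_per_module: int = 40
    terms_per_module: int = 30
    p_in: float = 0.6
    p_out: float = 0.02
    universe_factor: float = 2.0
    #: fraction of each module's terms named as signaling pathways
    #: (pathway-category terms), so the network stage has input.
    signaling_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError(f"need 0 <= p_out < p_in <= 1, got p_in={self.p_in} p_out={self.p_out}")
        if self.universe_factor < 2:
            raise ValueError("universe must be at least twice the query gene count")

    @property
    def n_genes(self) -> int:
        return self.n_modules * self.genes_per_module


@dataclass(frozen=True)
class PathwayParams:
    """Planted-hub bipartite generator settings."""

    n_genes: int = 200
    n_pathways: int = 40
    n_hubs: int = 10
    hub_rate: float = 0.6
    background_rate: float = 0.05
    n_uncovered: int = 3
    bridges_per_uncovered: int = 2

    def __post_init__(self) -> None:
        if self.n_pathways < 4:
            raise ValueError("need at least 4 pathways")
        if self.n_hubs < 1:
            raise ValueError("need at least one designated hub")
        if self.n_uncovered < 1:
            raise ValueError("need at least one designated uncovered pathway")
        if self.n_uncovered >= self.n_pathways:
            raise ValueError("uncovered pathways must leave covered pathways")
        needed = self.n_hubs + self.n_uncovered * self.bridges_per_uncovered
        if needed > self.n_genes:
            raise ValueError("not enough genes for designated hubs and bridges")


@dataclass
class SyntheticTruth:
    """Ground truth of a generator call: planted labels and parameters."""

    module_of: dict[str, int] = field(default_factory=dict)
    module_terms: dict[int, list[str]] = field(default_factory=dict)
    background_genes: list[str] = field(default_factory=list)
    hub_genes: list[str] = field(default_factory=list)
    bridge_genes: list[str] = field(default_factory=list)
    uncovered_pathways: list[str] = field(default_factory=list)
    bridge_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    seed: int = 0

    def module_partition(self) -> ClusterPartition:
        return ClusterPartition(assignments=dict(self.module_of))

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["bridge_pairs"] = [list(t) for t in self.bridge_pairs]
        return d


def simulate_annotation_catalog(
    params: ModuleParams = ModuleParams(), seed: int = 0
) -> tuple[list[str], AnnotationCatalog, GeneUniverse, SyntheticTruth]:
    """Generate a query gene list with planted annotation modules.

    Returns the query gene list (module order), the annotation catalog over
    the full universe, the universe itself, and the planted truth. Terms
    that end up with no carrier are silently dropped (they are untestable).
    """
    rng = np.random.default_rng(seed)
    categories = ("GO_BP", "KEGG_PATHWAY", "INTERPRO")

    query_genes = [
        f"GENE{m * params.genes_per_module + i + 1:04d}"
        for m in range(params.n_modules)
        for i in range(params.genes_per_module)
    ]
    n_background = int(np.ceil(params.n_genes * (params.universe_factor - 1)))
    background = [f"BKGD{i + 1:04d}" for i in range(n_background)]
    universe = GeneUniverse.from_iterable(query_genes + background)
    all_genes = np.array(query_genes + background)
    module_of = {
        g: m + 1
        for m in range(params.n_modules)
        for g in query_genes[m * params.genes_per_module:(m + 1) * params.genes_per_module]
    }

    n_signal = int(round(params.signaling_fraction * params.terms_per_module))
    terms: list[AnnotationTerm] = []
    module_terms: dict[int, list[str]] = {m + 1: [] for m in range(params.n_modules)}
    for m in range(params.n_modules):
        start = m * params.genes_per_module
        stop = start + params.genes_per_module
        for j in range(params.terms_per_module):
            if j < n_signal:
                term_id = f"M{m + 1:02d}_T{j + 1:02d} signaling pathway"
                category = "KEGG_PATHWAY"
            else:
                term_id = f"M{m + 1:02d}_T{j + 1:02d}"
                category = categories[j % len(categories)]
            carry = rng.random(all_genes.size) < params.p_out
            carry[start:stop] = rng.random(params.genes_per_module) < params.p_in
            members = frozenset(all_genes[carry])
            if not members:
                continue
            terms.append(AnnotationTerm(term_id, category, members))
            module_terms[m + 1].append(term_id)

    catalog = AnnotationCatalog(terms=terms, universe=universe)
    truth = SyntheticTruth(
        module_of=module_of,
        module_terms=module_terms,
        background_genes=background,
        params=asdict(params),
        seed=seed,
    )
    return query_genes, catalog, universe, truth


def simulate_pathway_membership(
    params: PathwayParams = PathwayParams(), seed: int = 0
) -> tuple[BipartiteNetwork, SyntheticTruth]:
    """Generate a bipartite gene-pathway network with planted hubs/bridges.

    Hub genes join each covered pathway with probability ``hub_rate``;
    ordinary genes with ``background_rate``. Designated uncovered pathways
    exclude all hubs by construction and receive designated bridge genes
    that also belong to at least one covered pathway. Every pathway is
    guaranteed at least one member (no isolated pathway nodes).
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:04d}" for i in range(params.n_genes)]
    hubs = genes[: params.n_hubs]
    non_hubs = genes[params.n_hubs:]
    n_covered = params.n_pathways - params.n_uncovered
    covered = [f"PATH{i + 1:03d}" for i in range(n_covered)]
    uncovered = [f"UPATH{i + 1:03d}" for i in range(params.n_uncovered)]

    memberships: set[tuple[str, str]] = set()
    for p in covered:
        for h in hubs:
            if rng.random() < params.hub_rate:
                memberships.add((h, p))
        for g in non_hubs:
            if rng.random() < params.background_rate:
                memberships.add((g, p))
        if not any(m[1] == p for m in memberships):
            memberships.add((str(rng.choice(non_hubs)), p))

    # every gene in a membership table has >= 1 pathway by definition
    # (degree-1 genes are common; isolated gene rows do not occur)
    for g in genes:
        if not any(m[0] == g for m in memberships):
            memberships.add((g, str(rng.choice(covered))))

    bridge_pool = list(non_hubs)
    rng.shuffle(bridge_pool)
    bridge_genes: list[str] = []
    bridge_pairs: list[tuple[str, str, str]] = []
    for p in uncovered:
        for _ in range(params.bridges_per_uncovered):
            b = bridge_pool.pop()
            anchor = str(rng.choice(covered))
            memberships.add((b, p))
            memberships.add((b, anchor))
            bridge_genes.append(b)
            bridge_pairs.append((b, p, anchor))
        # background members of the uncovered pathway (never hubs)
        for g in non_hubs:
            if rng.random() < params.background_rate:
                memberships.add((g, p))

    for h in hubs:
        for p in uncovered:
            if (h, p) in memberships:
                raise RuntimeError(f"constraint violated: hub {h} in uncovered pathway {p}")

    net = BipartiteNetwork.from_memberships(sorted(memberships))
    truth = SyntheticTruth(
        hub_genes=hubs,
        bridge_genes=sorted(set(bridge_genes)),
        uncovered_pathways=uncovered,
        bridge_pairs=bridge_pairs,
        params=asdict(params),
        seed=seed,
    )
    return net, truth


def _precision_recall(predicted: set[str], planted: set[str]) -> tuple[float, float]:
    tp = len(predicted & planted)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(planted) if planted else 1.0
    return precision, recall


def recovery_report(
    truth: SyntheticTruth,
    partition: ClusterPartition | None = None,
    communities: CommunityResult | None = None,
    hubs: set[str] | None = None,
    bridges: set[str] | None = None,
) -> dict:
    """Score recovered structure against the planted truth.

    Reports ARI of a cluster partition vs planted modules, hub
    precision/recall, bridge-gene recall, and ARI of detected communities
    vs planted modules (restricted to shared genes). Only metrics whose
    inputs were supplied are emitted.
    """
    from .clustering import partition_agreement

    report: dict = {"seed": truth.seed, "params": truth.params}
    if partition is not None:
        planted = truth.module_partition()
        report["module_ari"] = partition_agreement(partition, planted)
    if hubs is not None:
        precision, recall = _precision_recall(set(hubs), set(truth.hub_genes))
        report["hub_precision"] = precision
        report["hub_recall"] = recall
    if bridges is not None:
        _, recall = _precision_recall(set(bridges), set(truth.bridge_genes))
        report["bridge_recall"] = recall
    if communities is not None and truth.module_of:
        shared = sorted(set(communities.assignments) & set(truth.module_of))
        if shared:
            from sklearn.metrics import adjusted_rand_score

            a = [communities.assignments[g] for g in shared]
            b = [truth.module_of[g] for g in shared]
            report["community_module_ari"] = float(adjusted_rand_score(a, b))
    return report
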