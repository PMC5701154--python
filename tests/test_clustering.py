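"""Annotation matrix, Jaccard-Ward clustering, cuts, embeddings, ARI."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import squareform

from hairnet import (
    AnnotationCatalog,
    AnnotationMatrix,
    AnnotationTerm,
    ClusterPartition,
    GeneUniverse,
    build_annotation_matrix,
    cut_at_height,
    cut_to_k,
    enrich_catalog,
    jaccard_distances,
    partition_agreement,
    pca_reduce,
    tsne_embed,
    ward_linkage,
)
from hairnet.clustering import perplexity_sweep


def naive_ward_heights(dist_condensed: np.ndarray, n: int) -> np.ndarray:
    """O(n^3) Lance-Williams Ward agglomeration, independent of scipy.

    Repeatedly merges the closest active pair and updates distances with
    the Ward coefficients d(ij,k) = sqrt(((n_i+n_k) d_ik^2 + (n_j+n_k)
    d_jk^2 - n_k d_ij^2) / (n_i+n_j+n_k)). Raises if any merge choice is
    ambiguous (a tie at the minimum): tied instances admit several valid
    agglomerations, so a height-by-height comparison is only well-posed on
    tie-free inputs.
    """
    d = squareform(dist_condensed).astype(float)
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    heights = []
    while len(active) > 1:
        pairs = sorted((d[a, b], a, b) for a, b in itertools.combinations(active, 2))
        if len(pairs) > 1 and pairs[1][0] - pairs[0][0] < 1e-9:
            raise AssertionError("tied minimum merge distance: instance is ambiguous")
        h, i, j = pairs[0]
        heights.append(h)
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            new = np.sqrt(
                ((ni + nk) * d[i, k] ** 2 + (nj + nk) * d[j, k] ** 2 - nk * h ** 2)
                / (ni + nj + nk)
            )
            d[i, k] = d[k, i] = new
        sizes[i] = ni + nj
        active.remove(j)
    return np.array(heights)


class TestBuildMatrix:
    def test_direct_incidence(self, small_universe):
        catalog = AnnotationCatalog(
            terms=[
                AnnotationTerm("t1", "GO", frozenset({"G01", "G02"})),
                AnnotationTerm("t2", "GO", frozenset({"G02", "G03"})),
            ],
            universe=small_universe,
        )
        table = enrich_catalog(["G01", "G02", "G03"], catalog, small_universe, alpha=1.0)
        m = build_annotation_matrix(["G01", "G02", "G03"], table, catalog)
        frame = m.to_frame()
        assert frame.loc["G01"].tolist() == [1, 0] or frame.loc["G01"].tolist() == [0, 1]
        assert frame.loc["G02"].sum() == 2
        assert frame.values.sum() == 4

    def test_gene_without_significant_term_keeps_zero_row(self, small_universe):
        catalog = AnnotationCatalog(
            terms=[AnnotationTerm("t1", "GO", frozenset({"G01", "G02", "G03"}))],
            universe=small_universe,
        )
        table = enrich_catalog(["G01", "G02", "G03", "G09"], catalog, small_universe, alpha=1.0)
        m = build_annotation_matrix(["G01", "G02", "G03", "G09"], table, catalog)
        assert m.to_frame().loc["G09"].sum() == 0
        assert "G09" in m.genes

    def test_non_significant_term_column_absent(self, small_universe):
        catalog = AnnotationCatalog(
            terms=[
                AnnotationTerm("strong", "GO", frozenset({"G01", "G02", "G03", "G04"})),
                AnnotationTerm("weak", "GO", frozenset({"G01", "G15", "G16", "G17"})),
            ],
            universe=small_universe,
        )
        table = enrich_catalog(
            ["G01", "G02", "G03", "G04"], catalog, small_universe,
            method="hypergeometric", alpha=0.01,
        )
        m = build_annotation_matrix(["G01", "G02", "G03", "G04"], table, catalog)
        assert m.terms == ["strong"]

    def test_empty_inputs_error(self, small_universe, small_catalog, small_query):
        table = enrich_catalog(small_query, small_catalog, small_universe, alpha=1.0)
        with pytest.raises(ValueError):
            build_annotation_matrix([], table, small_catalog)


class TestJaccard:
    def test_reference_values(self):
        m = AnnotationMatrix(
            genes=["a", "b", "c", "d"],
            terms=["t1", "t2", "t3", "t4"],
            values=np.array(
                [[1, 1, 1, 0], [0, 1, 1, 1], [1, 1, 1, 0], [0, 0, 0, 1]]
            ),
        )
        d = squareform(jaccard_distances(m))
        assert d[0, 1] == pytest.approx(0.5)  # 1 - 2/4
        assert d[0, 2] == 0.0  # identical profiles
        assert d[0, 3] == 1.0  # disjoint profiles

    def test_all_zero_profile_conventions(self):
        m = AnnotationMatrix(
            genes=["a", "b", "c"],
            terms=["t1"],
            values=np.array([[0], [0], [1]]),
        )
        d = squareform(jaccard_distances(m))
        assert d[0, 1] == 0.0  # two unannotated genes are co-clusterable
        assert d[0, 2] == 1.0  # empty vs non-empty

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(11)
        profiles = rng.integers(0, 2, size=(3, 12, 10_000))
        inter = lambda x, y: (x & y).sum(axis=0)
        union = lambda x, y: (x | y).sum(axis=0)
        def dist(x, y):
            u = union(x, y)
            return np.where(u > 0, 1 - inter(x, y) / np.maximum(u, 1), 0.0)
        a, b, c = profiles
        dab, dbc, dac = dist(a, b), dist(b, c), dist(a, c)
        assert np.all(dac <= dab + dbc + 1e-12)


class TestWardLinkage:
    def test_two_points_merge_at_their_distance(self):
        dend = ward_linkage(np.array([0.37]), ["a", "b"])
        assert dend.heights[0] == pytest.approx(0.37)

    def test_separated_pairs_merge_first(self):
        # d12 = 0.1, d34 = 0.2, all cross distances 0.9
        d = squareform(
            np.array(
                [
                    [0.0, 0.1, 0.9, 0.9],
                    [0.1, 0.0, 0.9, 0.9],
                    [0.9, 0.9, 0.0, 0.2],
                    [0.9, 0.9, 0.2, 0.0],
                ]
            )
        )
        dend = ward_linkage(d, list("abcd"))
        first, second = dend.linkage[0], dend.linkage[1]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert {int(second[0]), int(second[1])} == {2, 3}

    @pytest.mark.parametrize("n,seed", [(5, 4), (5, 9), (6, 4), (6, 10)])
    def test_matches_naive_lance_williams_binary_profiles(self, n, seed):
        # seeds giving tie-free Jaccard instances (the oracle rejects ties)
        rng = np.random.default_rng(seed)
        profiles = rng.integers(0, 2, size=(n, 31))
        m = AnnotationMatrix(
            genes=[f"g{i}" for i in range(n)],
            terms=[f"t{j}" for j in range(31)],
            values=profiles,
        )
        d = jaccard_distances(m)
        dend = ward_linkage(d, m.genes)
        np.testing.assert_allclose(
            np.sort(dend.heights), np.sort(naive_ward_heights(d, n)), atol=1e-9
        )

    @pytest.mark.parametrize("n,seed", [(7, 0), (8, 1)])
    def test_matches_naive_lance_williams_continuous(self, n, seed):
        # continuous dissimilarities: ties have probability zero
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.05, 1.0, size=n * (n - 1) // 2)
        dend = ward_linkage(d, [f"g{i}" for i in range(n)])
        np.testing.assert_allclose(
            np.sort(dend.heights), np.sort(naive_ward_heights(d, n)), atol=1e-9
        )

    def test_nan_distances_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            ward_linkage(np.array([0.1, np.nan, 0.3]), ["a", "b", "c"])

    def test_merge_bookkeeping(self):
        rng = np.random.default_rng(5)
        m = AnnotationMatrix(
            genes=[f"g{i}" for i in range(9)],
            terms=[f"t{j}" for j in range(15)],
            values=rng.integers(0, 2, size=(9, 15)),
        )
        dend = ward_linkage(jaccard_distances(m), m.genes)
        assert dend.linkage.shape == (8, 4)
        assert dend.linkage[-1, 3] == 9  # final merge spans all genes
        assert dend.monotone


class TestCuts:
    @pytest.fixture
    def dend(self):
        rng = np.random.default_rng(4)
        m = AnnotationMatrix(
            genes=[f"g{i}" for i in range(12)],
            terms=[f"t{j}" for j in range(20)],
            values=rng.integers(0, 2, size=(12, 20)),
        )
        return ward_linkage(jaccard_distances(m), m.genes)

    def test_below_min_height_gives_singletons(self, dend):
        part = cut_at_height(dend, dend.heights.min() / 2)
        assert part.k == 12

    def test_above_max_height_gives_one_cluster(self, dend):
        part = cut_at_height(dend, dend.heights.max() * 1.01)
        assert part.k == 1

    def test_k_non_increasing_in_h(self, dend):
        hs = np.linspace(0, dend.heights.max() * 1.1, 25)
        ks = [cut_at_height(dend, h).k for h in hs]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_partition_conservation(self, dend):
        part = cut_at_height(dend, float(np.median(dend.heights)))
        assert sum(part.sizes().values()) == 12
        assert sorted(set(part.assignments.values())) == list(range(1, part.k + 1))

    def test_cut_to_k_exact(self, dend):
        for k in (1, 3, 6, 12):
            assert cut_to_k(dend, k).k == k

    def test_negative_height_rejected(self, dend):
        with pytest.raises(ValueError):
            cut_at_height(dend, -0.1)


class TestEmbeddings:
    @pytest.fixture
    def matrix(self):
        rng = np.random.default_rng(3)
        values = np.zeros((40, 30), dtype=int)
        values[:20, :15] = rng.random((20, 15)) < 0.8
        values[20:, 15:] = rng.random((20, 15)) < 0.8
        return AnnotationMatrix(
            genes=[f"g{i}" for i in range(40)],
            terms=[f"t{j}" for j in range(30)],
            values=values,
        )

    def test_rank_one_matrix_single_component(self):
        values = np.tile([1, 0, 1, 0, 1], (6, 1))
        values[0] = [0, 1, 0, 1, 0]
        m = AnnotationMatrix(
            genes=[f"g{i}" for i in range(6)],
            terms=[f"t{j}" for j in range(5)],
            values=values,
        )
        _, ratios = pca_reduce(m, n_components=4)
        assert ratios[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_conservation_and_monotone(self, matrix):
        scores, ratios = pca_reduce(matrix, n_components=30)
        assert ratios.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(ratios) <= 1e-12)

    def test_over_rank_request_truncates_with_warning(self, matrix):
        with pytest.warns(UserWarning, match="truncated"):
            scores, _ = pca_reduce(matrix, n_components=99)
        assert scores.shape[1] <= 30

    def test_tsne_deterministic_under_seed(self, matrix):
        scores, _ = pca_reduce(matrix, n_components=10)
        e1 = tsne_embed(scores, matrix.genes, perplexity=10, seed=42)
        e2 = tsne_embed(scores, matrix.genes, perplexity=10, seed=42)
        np.testing.assert_array_equal(e1.coordinates, e2.coordinates)

    def test_tsne_perplexity_bound(self, matrix):
        scores, _ = pca_reduce(matrix, n_components=10)
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(scores, matrix.genes, perplexity=40)

    def test_separated_modules_stay_separated(self):
        """Two planted modules from the generator: mean inter-module
        embedded distance exceeds mean intra-module distance for
        perplexities across the working range."""
        from hairnet import (
            ModuleParams,
            build_annotation_matrix,
            enrich_catalog,
            simulate_annotation_catalog,
        )

        params = ModuleParams(n_modules=2, genes_per_module=60, terms_per_module=30)
        genes, catalog, universe, truth = simulate_annotation_catalog(params, seed=0)
        table = enrich_catalog(genes, catalog, universe)
        matrix = build_annotation_matrix(genes, table, catalog)
        scores, _ = pca_reduce(matrix, n_components=20)
        labels = np.array([truth.module_of[g] for g in matrix.genes])
        for perplexity in (5, 30, 100):
            coords = tsne_embed(scores, matrix.genes, perplexity=perplexity, seed=0).coordinates
            from scipy.spatial.distance import pdist, squareform as sqf

            d = sqf(pdist(coords))
            same = labels[:, None] == labels[None, :]
            off_diag = ~np.eye(len(labels), dtype=bool)
            assert d[~same].mean() > d[same & off_diag].mean()

    def test_sweep_emits_one_embedding_per_value(self, matrix):
        scores, _ = pca_reduce(matrix, n_components=10)
        out = perplexity_sweep(scores, matrix.genes, perplexities=[5, 15, 30], seed=0)
        assert [e.perplexity for e in out] == [5, 15, 30]

    def test_partition_invariant_to_embedding_runs(self, matrix):
        """Clustering consumes the raw binary matrix; embeddings are
        diagnostics and cannot change the partition."""
        dend = ward_linkage(jaccard_distances(matrix), matrix.genes)
        before = cut_to_k(dend, 2)
        scores, _ = pca_reduce(matrix, n_components=10)
        tsne_embed(scores, matrix.genes, perplexity=10, seed=0)
        after = cut_to_k(ward_linkage(jaccard_distances(matrix), matrix.genes), 2)
        assert before.assignments == after.assignments


class TestPartitionAgreement:
    def test_identical_partitions(self):
        a = ClusterPartition({"g1": 1, "g2": 1, "g3": 2})
        b = ClusterPartition({"g1": 2, "g2": 2, "g3": 1})  # relabeled
        assert partition_agreement(a, b) == 1.0

    def test_singletons_vs_single_cluster(self):
        genes = [f"g{i}" for i in range(8)]
        a = ClusterPartition({g: i + 1 for i, g in enumerate(genes)})
        b = ClusterPartition({g: 1 for g in genes})
        assert partition_agreement(a, b) == 0.0

    def test_mismatched_gene_sets_rejected(self):
        a = ClusterPartition({"g1": 1, "g2": 2})
        b = ClusterPartition({"g1": 1, "g3": 2})
        with pytest.raises(ValueError):
            partition_agreement(a, b)

    def test_matches_pair_counting_oracle(self):
        """ARI recomputed from the raw contingency pair counts on a
        20-gene instance."""
        from math import comb

        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(20)]
        la = rng.integers(1, 4, size=20)
        lb = rng.integers(1, 5, size=20)
        a = ClusterPartition({g: int(v) for g, v in zip(genes, la)})
        b = ClusterPartition({g: int(v) for g, v in zip(genes, lb)})

        # contingency pair counts
        sum_ij = sum(
            comb(int(np.sum((la == i) & (lb == j))), 2)
            for i in np.unique(la)
            for j in np.unique(lb)
        )
        sum_a = sum(comb(int(np.sum(la == i)), 2) for i in np.unique(la))
        sum_b = sum(comb(int(np.sum(lb == j)), 2) for j in np.unique(lb))
        total = comb(20, 2)
        expected = sum_a * sum_b / total
        ari = (sum_ij - expected) / (0.5 * (sum_a + sum_b) - expected)
        assert partition_agreement(a, b) == pytest.approx(ari, abs=1e-12)
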