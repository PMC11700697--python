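"""Unsupervised characterization: z-scores, clustering, correlation networks."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from pasa.unsupervised import (
    betweenness,
    hierarchical_partition,
    pca_scores,
    reference_partition,
    shapiro_wilk,
    spearman_matrix,
    threshold_network,
    walktrap_communities,
    zscore,
)


class TestZscore:
    def test_closed_form_column(self):
        out = zscore(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.ravel(), [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        x = rng.normal(size=(40, 3))
        once = zscore(x)
        assert np.allclose(zscore(once), once, atol=1e-12)

    def test_random_matrix_standardized(self, rng):
        out = zscore(rng.normal(size=(100, 51)))
        assert np.all(np.abs(out.mean(axis=0)) < 1e-9)
        assert np.allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_constant_column_named(self):
        x = np.ones((10, 3))
        x[:, :2] = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError, match="index 2"):
            zscore(x)


class TestHierarchicalPartition:
    def test_duplicated_profiles_recovered_exactly(self, rng):
        """Two groups of identical wavelength profiles plus one distinct one."""
        base = rng.normal(size=(30, 2))
        profiles = np.hstack(
            [
                np.repeat(base[:, [0]], 3, axis=1) + 1e-9 * rng.normal(size=(30, 3)),
                np.repeat(base[:, [1]], 3, axis=1) + 1e-9 * rng.normal(size=(30, 3)),
                rng.normal(size=(30, 1)),
            ]
        )
        wl = 1200.0 + 10.0 * np.arange(7)
        part = hierarchical_partition(profiles, wl, k=3)
        segs = part.segments
        assert len(set(segs[:3])) == 1
        assert len(set(segs[3:6])) == 1
        assert segs[6] not in set(segs[:6])

    def test_k_one_single_segment(self, rng):
        wl = 1200.0 + 10.0 * np.arange(5)
        part = hierarchical_partition(rng.normal(size=(20, 5)), wl, k=1)
        assert len(set(part.segments)) == 1

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(ValueError):
            hierarchical_partition(rng.normal(size=(20, 5)), None, k=0)

    def test_recovers_planted_dominance(self, default_spectra, ground_truth_dominance):
        """>= 90% of wavelengths get their ground-truth dominant chromophore."""
        part = hierarchical_partition(default_spectra.values, default_spectra.wavelengths)
        agreement = np.mean(part.chromophore_labels() == ground_truth_dominance)
        assert agreement >= 0.9

    def test_invariant_to_sample_order_and_scale(self, default_spectra):
        values = default_spectra.values
        wl = default_spectra.wavelengths
        base = hierarchical_partition(values, wl)
        perm = np.random.default_rng(3).permutation(values.shape[0])
        shuffled = hierarchical_partition(values[perm], wl)
        scaled = hierarchical_partition(1e4 * values, wl)
        assert np.array_equal(base.chromophore_labels(), shuffled.chromophore_labels())
        assert np.array_equal(base.chromophore_labels(), scaled.chromophore_labels())


class TestReferencePartition:
    def test_bands(self):
        part = reference_partition()
        assert part.chromophore_of(1300.0) == "collagen"
        assert part.chromophore_of(1450.0) == "water"
        assert part.chromophore_of(1590.0) == "collagen"
        assert part.chromophore_of(1690.0) == "lipid"

    def test_every_wavelength_labeled_once(self):
        part = reference_partition()
        assert len(part.segments) == 51
        assert set(part.chromophores.values()) == {"collagen", "water", "lipid"}


class TestShapiroWilk:
    def test_normal_sample_passes(self, rng):
        _, p = shapiro_wilk(rng.normal(size=500))
        assert p > 0.05

    def test_uniform_sample_fails(self, rng):
        _, p = shapiro_wilk(rng.random(500))
        assert p < 0.01

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.array([1.0, 2.0]))


class TestSpearman:
    def test_monotone_invariance(self, rng):
        x = rng.normal(size=30)
        cm = spearman_matrix(np.column_stack([x, np.exp(x)]))
        assert cm[0, 1] == pytest.approx(1.0)

    def test_reversed_ranks(self):
        x = np.arange(20.0)
        cm = spearman_matrix(np.column_stack([x, x[::-1]]))
        assert cm[0, 1] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle_with_ties(self, rng):
        """Tie-corrected Spearman == Pearson of average ranks (brute force)."""
        x = rng.integers(0, 6, size=(20, 5)).astype(float)  # heavy ties
        cm = spearman_matrix(x)
        ranks = np.column_stack([stats.rankdata(x[:, j]) for j in range(5)])
        oracle = np.corrcoef(ranks, rowvar=False)
        assert np.abs(cm - oracle).max() < 1e-12

    def test_exactly_symmetric_unit_diagonal(self, default_spectra):
        cm = spearman_matrix(default_spectra.values)
        assert np.array_equal(cm, cm.T)
        assert np.all(np.diag(cm) == 1.0)

    def test_constant_column_rejected(self):
        x = np.ones((10, 2))
        x[:, 0] = np.arange(10.0)
        with pytest.raises(ValueError):
            spearman_matrix(x)


class TestThresholdNetwork:
    def test_complete_graph_above_threshold(self):
        n = 51
        cm = np.full((n, n), 0.95)
        np.fill_diagonal(cm, 1.0)
        g = threshold_network(cm)
        assert g.number_of_edges() == n * (n - 1) // 2

    def test_exact_threshold_excluded(self):
        cm = np.array([[1.0, 0.9], [0.9, 1.0]])
        assert threshold_network(cm, tau=0.9).number_of_edges() == 0

    def test_edge_count_matches_counting_oracle(self, rng):
        a = rng.uniform(-1, 1, size=(12, 12))
        cm = (a + a.T) / 2
        np.fill_diagonal(cm, 1.0)
        g = threshold_network(cm, tau=0.3)
        oracle = sum(
            1 for i, j in itertools.combinations(range(12), 2) if cm[i, j] > 0.3
        )
        assert g.number_of_edges() == oracle

    def test_monotone_in_tau(self, default_spectra):
        cm = spearman_matrix(default_spectra.values)
        counts = [
            threshold_network(cm, default_spectra.wavelengths, tau).number_of_edges()
            for tau in (0.5, 0.7, 0.9, 0.95)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            threshold_network(np.eye(3), tau=1.5)


class TestWalktrap:
    def test_two_cliques_recovered(self):
        g = nx.Graph()
        for offset in (0, 5):
            g.add_edges_from(
                (a + offset, b + offset) for a, b in itertools.combinations(range(5), 2)
            )
        g.add_edge(0, 5)
        communities = walktrap_communities(g)
        assert len(set(communities.values())) == 2
        assert len({communities[i] for i in range(5)}) == 1
        assert len({communities[i] for i in range(5, 10)}) == 1

    def test_complete_graph_single_community(self):
        g = nx.complete_graph(8)
        assert len(set(walktrap_communities(g).values())) == 1

    def test_edgeless_graph_all_singletons(self):
        g = nx.empty_graph(6)
        communities = walktrap_communities(g)
        assert len(set(communities.values())) == 6

    def test_largest_cancer_community_is_collagen_dominated(
        self, default_spectra, ground_truth_dominance
    ):
        """The biggest community of the cancer network sits in collagen bands."""
        cancer = default_spectra.subset_labels("cancer")
        cm = spearman_matrix(cancer.values)
        g = threshold_network(cm, default_spectra.wavelengths)
        communities = walktrap_communities(g)
        largest = max(
            set(communities.values()),
            key=lambda c: sum(1 for v in communities.values() if v == c),
        )
        members = [node for node, c in communities.items() if c == largest]
        dominance = dict(zip(default_spectra.wavelengths, ground_truth_dominance))
        collagen_members = sum(1 for m in members if dominance[m] == "collagen")
        assert collagen_members > len(members) / 2


class TestBetweenness:
    def test_path_graph(self):
        bc = betweenness(nx.path_graph(3))
        assert bc[1] == pytest.approx(1.0)
        assert bc[0] == bc[2] == 0.0

    def test_star_center(self):
        bc = betweenness(nx.star_graph(6))
        assert bc[0] == pytest.approx(1.0)

    def test_tiny_graph_all_zero(self):
        assert betweenness(nx.path_graph(2)) == {0: 0.0, 1: 0.0}

    def test_matches_bfs_enumeration_oracle(self):
        """Brute-force geodesic counting on seeded G(10, 0.4) graphs."""
        for seed in (1, 2, 3):
            g = nx.gnp_random_graph(10, 0.4, seed=seed)
            bc = betweenness(g)
            oracle = _brute_force_betweenness(g)
            for node in g.nodes:
                assert bc[node] == pytest.approx(oracle[node], abs=1e-9)


def _brute_force_betweenness(g: nx.Graph) -> dict:
    """Enumerate all shortest paths between every pair with pure BFS."""
    n = g.number_of_nodes()
    score = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in g.nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: s / norm for v, s in score.items()}


class TestPCA:
    def test_rank_one_matrix(self, rng):
        u = rng.normal(size=(30, 1))
        v = rng.normal(size=(1, 8))
        _, eigenvalues, _ = pca_scores(u @ v)
        assert eigenvalues[0] / eigenvalues.sum() > 1.0 - 1e-9

    def test_trace_identity(self, rng):
        x = zscore(rng.normal(size=(60, 12)))
        _, eigenvalues, _ = pca_scores(x)
        assert eigenvalues.sum() == pytest.approx(12.0, abs=1e-9)

    def test_matches_svd_oracle_up_to_sign(self, rng):
        x = zscore(rng.normal(size=(40, 6)))
        scores, _, _ = pca_scores(x)
        centered = x - x.mean(axis=0)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        oracle = u * s
        for j in range(scores.shape[1]):
            assert min(
                np.abs(scores[:, j] - oracle[:, j]).max(),
                np.abs(scores[:, j] + oracle[:, j]).max(),
            ) < 1e-9
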