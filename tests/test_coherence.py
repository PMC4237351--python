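import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from netnoise.coherence import (
    coherence_scan,
    default_cutoff_grid,
    empirical_p,
    random_null,
    scan_to_frame,
    topology_metrics,
)
from netnoise.model import NetworkGwas


class TestTopologyMetrics:
    def test_fully_connected_path(self, path_graph):
        m = topology_metrics(path_graph, {"a", "b", "c"})
        assert (m.pct_direct, m.pct_isolated, m.lcc_size) == (100.0, 0.0, 3)

    def test_no_within_set_edges(self, path_graph):
        m = topology_metrics(path_graph, {"a", "c"})
        assert (m.pct_direct, m.pct_isolated, m.lcc_size) == (0.0, 100.0, 1)

    def test_triangle_plus_isolate_hand_count(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        g.add_node("d")
        m = topology_metrics(g, {"a", "b", "c", "d"})
        assert m.pct_isolated == 25.0 and m.pct_direct == 75.0
        assert m.edge_density == pytest.approx(3 / 6)
        assert m.lcc_size == 3

    def test_empty_subset_all_zero(self, path_graph):
        m = topology_metrics(path_graph, set())
        assert (m.n_selected, m.pct_direct, m.pct_isolated, m.lcc_size) == (0, 0, 0, 0)

    @given(st.integers(min_value=1, max_value=40), st.integers(min_value=0, max_value=10**6))
    def test_direct_and_isolated_sum_to_100(self, k, seed):
        g = nx.gnp_random_graph(40, 0.1, seed=seed % 1000)
        rng = np.random.default_rng(seed)
        subset = set(rng.choice(40, size=k, replace=False).tolist())
        m = topology_metrics(g, subset)
        assert m.pct_direct + m.pct_isolated == pytest.approx(100.0)
        assert m.lcc_size <= m.n_selected


class TestEmpiricalP:
    def test_hand_count(self):
        assert empirical_p(5, [1, 2, 3], "greater") == pytest.approx(1 / 4)

    def test_all_null_tied_with_observed(self):
        assert empirical_p(2.0, [2.0] * 9, "greater") == 1.0
        assert empirical_p(2.0, [2.0] * 9, "smaller") == 1.0

    def test_observed_below_all_null(self):
        null = list(range(10, 20))
        assert empirical_p(1, null, "greater") == 1.0
        assert empirical_p(1, null, "smaller") == pytest.approx(1 / 11)

    def test_never_zero_floor(self):
        null = np.arange(1000)
        assert empirical_p(10**9, null, "greater") == pytest.approx(1 / 1001)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_p(1.0, [], "greater")

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=50),
           st.floats(0, 100, allow_nan=False))
    def test_in_unit_interval_and_directions_cover(self, null, obs):
        pg = empirical_p(obs, null, "greater")
        ps = empirical_p(obs, null, "smaller")
        n = len(null)
        assert 1 / (n + 1) <= pg <= 1.0 and 1 / (n + 1) <= ps <= 1.0
        # every null value is >= or <= observed, possibly both (ties)
        assert pg + ps >= (n + 2) / (n + 1)


class TestRandomNull:
    def test_reproducible_and_seed_sensitive(self, rng):
        g = nx.gnp_random_graph(50, 0.1, seed=1)
        a = random_null(g, 10, n_perm=20, seed=42)
        b = random_null(g, 10, n_perm=20, seed=42)
        c = random_null(g, 10, n_perm=20, seed=43)
        assert all(np.array_equal(a[k], b[k]) for k in a)
        assert any(not np.array_equal(a[k], c[k]) for k in a)

    def test_full_node_set_has_zero_variance(self):
        g = nx.gnp_random_graph(20, 0.2, seed=2)
        null = random_null(g, 20, n_perm=10, seed=0)
        for vals in null.values():
            assert np.ptp(vals) == 0

    def test_set_size_exceeding_universe_rejected(self):
        g = nx.gnp_random_graph(5, 0.5, seed=0)
        with pytest.raises(ValueError):
            random_null(g, 6, n_perm=5, seed=0)

    def test_uniform_sampling_frequencies(self):
        # 10-node graph, sets of 3: each node should appear ~30% of draws
        g = nx.path_graph(10)
        freq = np.zeros(10)
        rng = np.random.default_rng(99)
        n_draws = 10_000
        for _ in range(n_draws):
            idx = rng.choice(10, size=3, replace=False)
            freq[idx] += 1
        # oracle for the sampler used inside random_null
        assert np.all(np.abs(freq / n_draws - 0.3) < 0.02)

    def test_degree_matched_preserves_decile_profile(self):
        g = nx.barabasi_albert_graph(200, 3, seed=5)
        match = set(range(0, 40))
        null = random_null(g, len(match), n_perm=5, seed=1,
                           mode="degree_matched", match_set=match)
        assert all(len(v) == 5 for v in null.values())


class TestScan:
    def test_scan_on_planted_module(self, small_dataset):
        model = NetworkGwas.from_synthetic(small_dataset)
        from netnoise.scoring import score_genes

        scores = score_genes(model.snps, model.genes)
        results = coherence_scan(
            scores, model.gene_protein_map, model.network,
            cutoffs=[0.5, 1.0, 1.5], n_perm=100, seed=2,
        )
        assert [r.cutoff_neglogp for r in results] == [0.5, 1.0, 1.5]
        at_1 = results[1]
        assert at_1.empirical_p["lcc_size"] <= 0.05
        for r in results:
            assert all(len(v) == 100 for v in r.null_samples.values())

    def test_scan_truncates_when_selection_empties(self, path_graph):
        from netnoise.scoring import GeneScore

        scores = [
            GeneScore(gene_id=g, best_snp_p=p, n_snps=1,
                      corrected_p=p, neg_log10_p=-np.log10(p))
            for g, p in [("g1", 0.05), ("g2", 0.2)]
        ]
        gp = [("g1", "a"), ("g2", "b")]
        results = coherence_scan(scores, gp, path_graph,
                                 cutoffs=[0.5, 1.0, 2.0], n_perm=10, seed=0)
        assert [r.cutoff_neglogp for r in results] == [0.5, 1.0]

    def test_unsorted_cutoffs_rejected(self, path_graph):
        with pytest.raises(ValueError):
            coherence_scan([], [], path_graph, cutoffs=[1.0, 0.5])

    def test_default_grid(self):
        grid = default_cutoff_grid()
        assert grid[0] == 0.5 and grid[-1] == 5.0 and len(grid) == 10

    def test_scan_frame_columns(self, fitted):
        df = scan_to_frame(fitted.scan)
        assert "lcc_size_observed" in df.columns
        assert "lcc_size_empirical_p" in df.columns
        assert (df["n_selected"] > 0).all()
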