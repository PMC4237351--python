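import networkx as nx
import numpy as np
import pytest
from scipy import stats

from netnoise.scoring import assign_snps_to_genes
from netnoise.simulate import (
    SyntheticConfig,
    generate_dataset,
    generate_pair,
    make_candidates,
    make_network,
    write_dataset,
)

SMALL = SyntheticConfig(
    n_proteins=300, n_genes=400, module_size=20, n_intergenic_snps=500,
    n_candidates=20, seed=3,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"module_size": 0},
            {"module_size": 5000},
            {"n_proteins": 5000},          # > n_genes
            {"signal_fraction": 1.5},
            {"signal_beta": 0.0},
            {"module_edge_boost": 0.5},
            {"candidate_overlap": -0.1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        import yaml

        with open(p, "w") as fh:
            yaml.safe_dump(SMALL.to_dict(), fh)
        assert SyntheticConfig.from_yaml(p) == SMALL


class TestNetwork:
    def test_planted_module_is_connected(self):
        g, module = make_network(SMALL)
        assert len(module) == SMALL.module_size
        assert nx.is_connected(g.subgraph(module))

    def test_same_seed_same_graph(self):
        g1, m1 = make_network(SMALL)
        g2, m2 = make_network(SMALL)
        assert m1 == m2 and nx.utils.graphs_equal(g1, g2)

    def test_huge_boost_makes_clique(self):
        cfg = SyntheticConfig(
            n_proteins=300, n_genes=400, module_size=5,
            module_edge_boost=1e9, seed=1,
        )
        g, module = make_network(cfg)
        sub = g.subgraph(module)
        assert sub.number_of_edges() == 5 * 4 // 2

    def test_barabasi_albert_model(self):
        cfg = SyntheticConfig(
            n_proteins=300, n_genes=400, module_size=10,
            edge_model="barabasi_albert", ba_m=3, seed=2,
        )
        g, module = make_network(cfg)
        assert g.number_of_nodes() == 300
        assert nx.is_connected(g.subgraph(module))


class TestAssociation:
    def test_deterministic_regeneration(self):
        ds1 = generate_dataset(SMALL)
        ds2 = generate_dataset(SMALL)
        assert ds1.snps == ds2.snps
        assert ds1.candidates == ds2.candidates
        assert ds1.gene_protein_map == ds2.gene_protein_map

    def test_gene_layout_windows_never_overlap(self):
        ds = generate_dataset(SMALL)
        by_chrom = {}
        for g in ds.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        w = SMALL.window_bp
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.start)
            for a, b in zip(genes, genes[1:]):
                assert a.end + w < b.start - w

    def test_genic_snps_assign_to_exactly_one_gene(self):
        ds = generate_dataset(SMALL)
        assigned = assign_snps_to_genes(ds.snps, ds.genes,
                                        window_bp=SMALL.window_bp)
        counts = {}
        for recs in assigned.values():
            for r in recs:
                counts[r.snp_id] = counts.get(r.snp_id, 0) + 1
        assert counts and max(counts.values()) == 1
        n_genic = len(ds.snps) - SMALL.n_intergenic_snps
        assert len(counts) == n_genic  # intergenic SNPs stay unassigned

    def test_null_pvalues_uniform(self):
        cfg = SyntheticConfig(
            n_proteins=300, n_genes=2000, module_size=20, signal_beta=1.0,
            n_intergenic_snps=0, n_candidates=20, seed=9,
        )
        ds = generate_dataset(cfg)
        pvals = np.array([s.pvalue for s in ds.snps])
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_signal_pvalues_follow_beta_cdf(self):
        ds = generate_dataset(SMALL)
        assigned = assign_snps_to_genes(ds.snps, ds.genes, window_bp=0)
        signal_p = np.array(
            [r.pvalue for g in ds.signal_genes for r in assigned.get(g, [])]
        )
        b = SMALL.signal_beta
        # closed-form CDF of Beta(b, 1) is x**b
        assert stats.kstest(signal_p, lambda x: x**b).pvalue > 1e-3
        # enrichment: far more sub-0.1 signal p-values than the uniform rate
        assert (signal_p < 0.1).mean() > 3 * 0.1

    def test_expected_best_snp_enrichment_matches_beta_arithmetic(self):
        # P(best of k signal SNPs < 0.1) = 1 - (1 - 0.1**b)**k
        cfg = SyntheticConfig(
            n_proteins=400, n_genes=500, module_size=200, signal_fraction=1.0,
            n_intergenic_snps=0, n_candidates=20, seed=21,
        )
        ds = generate_dataset(cfg)
        assigned = assign_snps_to_genes(ds.snps, ds.genes, window_bp=0)
        hits, expect = [], []
        for g in ds.signal_genes:
            recs = assigned[g]
            hits.append(min(r.pvalue for r in recs) < 0.1)
            expect.append(1 - (1 - 0.1**cfg.signal_beta) ** len(recs))
        assert np.mean(hits) == pytest.approx(np.mean(expect), abs=0.05)


class TestCandidatesAndPair:
    def test_exact_overlap_construction(self, rng):
        module = [f"G{i:05d}" for i in range(30)]
        others = [f"G{i:05d}" for i in range(30, 400)]
        cfg = SyntheticConfig(
            n_proteins=300, n_genes=400, module_size=30,
            candidate_overlap=0.5, n_candidates=20, seed=0,
        )
        cand = make_candidates(module, cfg, module + others, rng)
        assert len(cand) == 20
        assert len(cand & set(module)) == 10

    def test_zero_and_full_overlap(self, rng):
        module = [f"G{i:05d}" for i in range(30)]
        all_genes = [f"G{i:05d}" for i in range(400)]
        base = dict(n_proteins=300, n_genes=400, module_size=30, seed=0)
        none = make_candidates(
            module, SyntheticConfig(**base, candidate_overlap=0.0,
                                    n_candidates=20), all_genes, rng)
        assert none.isdisjoint(module)
        full = make_candidates(
            module, SyntheticConfig(**base, candidate_overlap=1.0,
                                    n_candidates=30), all_genes, rng)
        assert full == set(module)

    def test_overlap_exceeding_module_rejected(self, rng):
        cfg = SyntheticConfig(n_proteins=300, n_genes=400, module_size=5,
                              candidate_overlap=1.0, n_candidates=20, seed=0)
        with pytest.raises(ValueError):
            make_candidates([f"G{i}" for i in range(5)], cfg,
                            [f"G{i}" for i in range(400)], rng)

    def test_pair_shares_structure_not_noise(self):
        ds1, ds2 = generate_pair(SMALL)
        assert nx.utils.graphs_equal(ds1.network, ds2.network)
        assert ds1.module_genes == ds2.module_genes
        assert ds1.genes == ds2.genes
        p1 = [s.pvalue for s in ds1.snps]
        p2 = [s.pvalue for s in ds2.snps]
        assert p1 != p2


class TestWriteDataset:
    def test_emitted_files_round_trip_through_readers(self, tmp_path):
        from netnoise import io as nio

        ds = generate_dataset(SMALL)
        paths = write_dataset(ds, tmp_path / "sim")
        snps, _ = nio.read_association_table(paths["association"])
        assert len(snps) == len(ds.snps)
        net, _ = nio.read_edge_list(paths["network"])
        assert nx.utils.graphs_equal(net, ds.network)
        genes, _ = nio.read_gene_annotation(paths["genes"])
        assert genes == ds.genes
        pairs, _ = nio.read_gene_protein_map(paths["map"])
        assert sorted(pairs) == sorted(ds.gene_protein_map)
        cand, _ = nio.read_gene_list(paths["candidates"])
        assert cand == ds.candidates
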