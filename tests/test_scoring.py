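import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from netnoise.io import GeneAnnotation, SnpRecord
from netnoise.scoring import (
    assign_snps_to_genes,
    best_snp_pvalue,
    correct_gene_scores,
    score_genes,
)


def snp(i, pos, p=0.5, chrom="1"):
    return SnpRecord(f"rs{i}", chrom, pos, p)


GENE = GeneAnnotation("gA", "1", 100_000, 200_000)


class TestAssignment:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (195_000, True),   # inside the gene body
            (210_000, True),   # exactly end + window
            (210_001, False),  # one past the window
            (90_000, True),    # exactly start - window
            (89_999, False),
        ],
    )
    def test_window_boundary(self, pos, expected):
        assigned = assign_snps_to_genes([snp(1, pos)], [GENE], window_bp=10_000)
        assert ("gA" in assigned) is expected

    def test_window_zero_keeps_only_in_gene_snps(self):
        snps = [snp(1, 99_999), snp(2, 100_000), snp(3, 200_000), snp(4, 200_001)]
        assigned = assign_snps_to_genes(snps, [GENE], window_bp=0)
        assert {r.snp_id for r in assigned["gA"]} == {"rs2", "rs3"}

    def test_other_chromosome_never_assigned(self):
        assigned = assign_snps_to_genes([snp(1, 150_000, chrom="2")], [GENE])
        assert assigned == {}

    def test_snp_in_two_overlapping_genes(self):
        g2 = GeneAnnotation("gB", "1", 150_000, 250_000)
        assigned = assign_snps_to_genes([snp(1, 180_000)], [GENE, g2], window_bp=0)
        assert set(assigned) == {"gA", "gB"}

    @given(st.integers(min_value=0, max_value=50_000), st.integers(min_value=0, max_value=50_000))
    def test_assignment_monotone_in_window(self, w1, w2):
        lo, hi = sorted((w1, w2))
        snps = [snp(i, 80_000 + 5_000 * i) for i in range(30)]
        a_lo = assign_snps_to_genes(snps, [GENE], window_bp=lo)
        a_hi = assign_snps_to_genes(snps, [GENE], window_bp=hi)
        small = {r.snp_id for r in a_lo.get("gA", [])}
        big = {r.snp_id for r in a_hi.get("gA", [])}
        assert small <= big


class TestBestSnp:
    def test_minimum_and_count(self):
        assigned = {"g": [snp(1, 1, 0.5), snp(2, 2, 0.01), snp(3, 3, 0.2)]}
        assert best_snp_pvalue(assigned)["g"][:2] == (0.01, 3)

    def test_singleton_and_tie(self):
        assigned = {
            "g1": [snp(1, 1, 0.7)],
            "g2": [snp(3, 3, 0.05), snp(2, 2, 0.05)],
            "g3": [],
        }
        best = best_snp_pvalue(assigned)
        assert best["g1"] == (0.7, 1, "rs1")
        assert best["g2"] == (0.05, 2, "rs2")  # lexicographic tie-break
        assert "g3" not in best


def make_raw(n, rng, confounded=False):
    spk = rng.uniform(0.5, 5.0, size=n)
    if confounded:
        y = 2.0 * spk + rng.normal(0, 0.3, size=n)
        best_p = 10.0 ** (-np.clip(y, 0.01, 300))
    else:
        best_p = rng.uniform(1e-6, 1.0, size=n)
    return [
        (
            f"g{i:05d}",
            float(best_p[i]),
            {"gene_size_kb": float(rng.uniform(1, 100)),
             "n_snps": float(rng.integers(1, 30)),
             "snps_per_kb": float(spk[i])},
        )
        for i in range(n)
    ]


class TestCorrection:
    def test_corrected_p_is_exact_rank_grid(self, rng):
        raw = make_raw(50, rng)
        scores = correct_gene_scores(raw)
        grid = sorted(s.corrected_p for s in scores)
        assert grid == [i / 51 for i in range(1, 51)]
        assert all(0 < s.corrected_p < 1 for s in scores)

    def test_constant_covariates_preserve_best_p_order(self, rng):
        raw = [
            (g, p, {"gene_size_kb": 10.0, "n_snps": 5.0, "snps_per_kb": 0.5})
            for g, p, _ in make_raw(40, rng)
        ]
        scores = correct_gene_scores(raw)
        by_raw = sorted(scores, key=lambda s: s.best_snp_p)
        by_corr = sorted(scores, key=lambda s: s.corrected_p)
        assert [s.gene_id for s in by_raw] == [s.gene_id for s in by_corr]

    def test_confounder_is_regressed_out(self, rng):
        raw = make_raw(2000, rng, confounded=True)
        scores = correct_gene_scores(raw)
        spk = np.array([s.covariates["snps_per_kb"] for s in scores])
        cp = np.array([s.corrected_p for s in scores])
        rho_before = stats.spearmanr(
            spk, [s.best_snp_p for s in scores]
        ).statistic
        rho_after = stats.spearmanr(spk, cp).statistic
        assert abs(rho_before) > 0.9  # the confounding is real
        assert abs(rho_after) < 0.1   # and removed by the correction

    def test_too_few_genes_refused(self, rng):
        with pytest.raises(ValueError, match=">= 10"):
            correct_gene_scores(make_raw(5, rng))


class TestScoreGenes:
    def test_null_fraction_below_cutoff_is_nominal(self, rng):
        # uniform SNP p-values: exactly rank-based corrected p at ~10%
        genes = [
            GeneAnnotation(f"g{i}", "1", 1 + 100_000 * i, 50_000 + 100_000 * i)
            for i in range(200)
        ]
        snps = [
            SnpRecord(f"rs{i}_{j}", "1", 1 + 100_000 * i + 250 * j,
                      float(rng.uniform(1e-12, 1)))
            for i in range(200)
            for j in range(int(rng.integers(2, 20)))
        ]
        scores = score_genes(snps, genes)
        frac = np.mean([s.corrected_p < 0.1 for s in scores])
        assert frac == pytest.approx(0.1, abs=0.01)

    def test_genes_without_snps_excluded(self):
        genes = [
            GeneAnnotation(f"g{i}", "1", 1 + 100_000 * i, 50_000 + 100_000 * i)
            for i in range(12)
        ] + [GeneAnnotation("gEmpty", "9", 1, 1000)]
        snps = [snp(i, 1 + 100_000 * i + 10, 0.2 + 0.01 * i) for i in range(12)]
        scores = score_genes(snps, genes)
        assert {s.gene_id for s in scores} == {f"g{i}" for i in range(12)}
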