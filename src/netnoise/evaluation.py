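"""Benchmarking gene selections against a candidate list and across datasets.

Precision is the fraction of selected genes that are known candidates;
recall is the fraction of known candidates retrieved.  The LCC gene set
is compared with two baselines drawn from the same scored gene list:
all genes at the same cutoff, and the equally-sized set of top-ranked
genes.  Cross-dataset reproducibility is quantified with the Jaccard
index at SNP, gene and LCC level, using per-dataset top-N lists with
N equal to each dataset's LCC size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import SnpRecord
from .scoring import GeneScore

__all__ = [
    "EvaluationResult",
    "OverlapResult",
    "precision_recall",
    "build_selections",
    "jaccard",
    "top_n_genes",
    "top_n_snps",
    "cross_dataset_overlap",
]


@dataclass(frozen=True)
class EvaluationResult:
    """Precision/recall of one gene selection against a candidate list."""

    selection_label: str
    n_selected: int
    n_hits: int
    precision_pct: float
    recall_pct: float


@dataclass(frozen=True)
class OverlapResult:
    """Jaccard overlap between two datasets at one level of analysis."""

    level: str  # snp | gene | lcc
    jaccard: float
    n_intersection: int
    n_union: int


def _norm(gene_id: str) -> str:
    return str(gene_id).strip().upper()


def precision_recall(
    selected: Iterable[str],
    candidates: Iterable[str],
    selection_label: str = "selection",
) -> EvaluationResult:
    """Precision and recall (%) of a gene selection against known candidates.

    Matching is by exact gene id after case normalization; duplicates and
    ordering in either input are irrelevant.
    """
    sel = {_norm(g) for g in selected}
    cand = {_norm(g) for g in candidates}
    if not sel:
        raise ValueError("selected set is empty: precision undefined")
    if not cand:
        raise ValueError("candidate list is empty: recall undefined")
    hits = len(sel & cand)
    return EvaluationResult(
        selection_label=selection_label,
        n_selected=len(sel),
        n_hits=hits,
        precision_pct=100.0 * hits / len(sel),
        recall_pct=100.0 * hits / len(cand),
    )


def top_n_genes(scores: Sequence[GeneScore], n: int) -> set[str]:
    """The n most significant genes by corrected p (ties by gene id)."""
    if n > len(scores):
        raise ValueError(f"requested top {n} of only {len(scores)} scored genes")
    ranked = sorted(scores, key=lambda s: (s.corrected_p, s.gene_id))
    return {s.gene_id for s in ranked[:n]}


def top_n_snps(snps: Sequence[SnpRecord], n: int) -> set[str]:
    """The n most significant SNP ids by association p (ties by SNP id)."""
    if n > len(snps):
        raise ValueError(f"requested top {n} of only {len(snps)} SNPs")
    ranked = sorted(snps, key=lambda s: (s.pvalue, s.snp_id))
    return {s.snp_id for s in ranked[:n]}


def build_selections(
    scores: Sequence[GeneScore],
    lcc_genes: set[str],
    cutoff_neglogp: float,
) -> dict[str, set[str]]:
    """The three benchmark selections: LCC genes, top genes, all at cutoff.

    ``top_genes`` has the same size as the LCC gene set, ranked by
    corrected gene-wise p (deterministic tie-break by gene id);
    ``all_at_cutoff`` is every gene meeting the cutoff.  The LCC genes
    must be a subset of the cutoff selection.
    """
    from .network import select_genes

    all_at_cutoff = select_genes(scores, cutoff_neglogp)
    if not lcc_genes <= all_at_cutoff:
        raise ValueError(
            "LCC genes are not a subset of the cutoff selection: "
            f"{sorted(lcc_genes - all_at_cutoff)[:5]}..."
        )
    return {
        "lcc_genes": set(lcc_genes),
        "top_genes": top_n_genes(scores, len(lcc_genes)),
        "all_at_cutoff": all_at_cutoff,
    }


def jaccard(a: Iterable, b: Iterable, level: str = "gene") -> OverlapResult:
    """Jaccard index |A∩B| / |A∪B| of two sets."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    inter = sa & sb
    return OverlapResult(
        level=level,
        jaccard=len(inter) / len(union),
        n_intersection=len(inter),
        n_union=len(union),
    )


def cross_dataset_overlap(
    snps1: Sequence[SnpRecord],
    scores1: Sequence[GeneScore],
    lcc_genes1: set[str],
    snps2: Sequence[SnpRecord],
    scores2: Sequence[GeneScore],
    lcc_genes2: set[str],
) -> tuple[list[OverlapResult], Mapping[str, float]]:
    """Dataset overlap at SNP, gene and LCC level, plus fold-change ratios.

    Each dataset contributes its top-N SNPs and top-N genes with N equal
    to that dataset's LCC gene count, so all three comparisons involve
    equally sized per-dataset lists.  Fold changes are the ratios
    ``jaccard_lcc / jaccard_snp`` and ``jaccard_lcc / jaccard_gene``
    (infinite when the denominator overlap is zero).
    """
    if not lcc_genes1 or not lcc_genes2:
        raise ValueError("cross-dataset overlap requires non-empty LCCs")
    n1, n2 = len(lcc_genes1), len(lcc_genes2)
    results = [
        jaccard(top_n_snps(snps1, n1), top_n_snps(snps2, n2), level="snp"),
        jaccard(top_n_genes(scores1, n1), top_n_genes(scores2, n2), level="gene"),
        jaccard(lcc_genes1, lcc_genes2, level="lcc"),
    ]
    by_level = {r.level: r.jaccard for r in results}
    folds = {
        "lcc_vs_snp": (
            by_level["lcc"] / by_level["snp"] if by_level["snp"] else float("inf")
        ),
        "lcc_vs_gene": (
            by_level["lcc"] / by_level["gene"] if by_level["gene"] else float("inf")
        ),
    }
    return results, folds
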