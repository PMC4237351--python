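"""Gene-wise association scores from per-SNP p-values.

A gene's raw score is the most significant p-value among the SNPs mapped
to it (within the gene body or up to ``window_bp`` on either side).  The
best-SNP p-value is strongly confounded by gene size and SNP density —
longer, denser genes draw more minima — so a MAGENTA-like correction is
applied: forward-stepwise OLS regresses -log10(best p) on gene-level
covariates, and the residuals are mapped back to a valid p-value scale by
an empirical rank-to-uniform transform.  The corrected p-values are exact
ranks ``i/(N+1)``: they preserve the residual ordering, never hit 0 or 1,
and are uniform by construction under the null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import GeneAnnotation, SnpRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GeneScore",
    "assign_snps_to_genes",
    "best_snp_pvalue",
    "correct_gene_scores",
    "score_genes",
    "scores_to_frame",
]

#: Covariates computed from the assignment itself (others may be user-supplied).
DEFAULT_COVARIATES = ("gene_size_kb", "n_snps", "snps_per_kb")

MIN_GENES_FOR_CORRECTION = 10


@dataclass(frozen=True)
class GeneScore:
    """Per-gene best-SNP p-value with its confounder-corrected p."""

    gene_id: str
    best_snp_p: float
    n_snps: int
    covariates: Mapping[str, float] = field(default_factory=dict)
    corrected_p: float = float("nan")
    neg_log10_p: float = float("nan")
    best_snp_id: str = ""


def assign_snps_to_genes(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneAnnotation],
    window_bp: int = 10_000,
) -> dict[str, list[SnpRecord]]:
    """Assign each SNP to every gene whose ±window extends over it.

    A SNP at position ``pos`` on the gene's chromosome is assigned iff
    ``start - window_bp <= pos <= end + window_bp``; a SNP inside two
    overlapping windows appears in both bins.  Genes with no SNPs get no
    entry.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    by_chrom: dict[str, list[SnpRecord]] = {}
    for snp in snps:
        by_chrom.setdefault(snp.chrom, []).append(snp)
    pos_arrays: dict[str, np.ndarray] = {}
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: r.pos)
        pos_arrays[chrom] = np.fromiter((r.pos for r in recs), dtype=np.int64)

    assigned: dict[str, list[SnpRecord]] = {}
    n_assigned_ids: set[str] = set()
    for gene in genes:
        recs = by_chrom.get(gene.chrom)
        if not recs:
            continue
        positions = pos_arrays[gene.chrom]
        lo = int(np.searchsorted(positions, gene.start - window_bp, side="left"))
        hi = int(np.searchsorted(positions, gene.end + window_bp, side="right"))
        if hi > lo:
            hits = recs[lo:hi]
            assigned[gene.gene_id] = list(hits)
            n_assigned_ids.update(r.snp_id for r in hits)
    n_unassigned = len(snps) - len(n_assigned_ids)
    logger.info(
        "assigned %d/%d SNPs to %d genes (window %d bp); %d unassigned",
        len(n_assigned_ids), len(snps), len(assigned), window_bp, n_unassigned,
    )
    return assigned


def best_snp_pvalue(
    assigned: Mapping[str, Sequence[SnpRecord]],
) -> dict[str, tuple[float, int, str]]:
    """Per gene: (minimum p among assigned SNPs, SNP count, best SNP id).

    Empty bins are excluded silently.  When several SNPs tie at the
    minimum the lexicographically smallest SNP id is reported (the value,
    not the identity, is what downstream scoring uses).
    """
    out: dict[str, tuple[float, int, str]] = {}
    for gene_id, recs in assigned.items():
        if not recs:
            continue
        best = min(recs, key=lambda r: (r.pvalue, r.snp_id))
        out[gene_id] = (best.pvalue, len(recs), best.snp_id)
    return out


def _forward_stepwise(y: np.ndarray, X: pd.DataFrame) -> list[str]:
    """Forward variable selection by AIC on an OLS fit (constant always in)."""
    remaining = list(X.columns)
    selected: list[str] = []
    current_aic = sm.OLS(y, np.ones((len(y), 1))).fit().aic
    while remaining:
        scores = []
        for name in remaining:
            cols = selected + [name]
            design = sm.add_constant(X[cols].to_numpy(), has_constant="add")
            if np.linalg.matrix_rank(design) < design.shape[1]:
                continue  # collinear with what's already in
            aic = sm.OLS(y, design).fit().aic
            scores.append((aic, name))
        if not scores:
            break
        scores.sort()
        best_aic, best_name = scores[0]
        if best_aic < current_aic - 1e-9:
            selected.append(best_name)
            remaining.remove(best_name)
            current_aic = best_aic
        else:
            break
    return selected


def correct_gene_scores(
    raw: Iterable[tuple[str, float, Mapping[str, float]]],
    covariates: Sequence[str] | None = None,
) -> list[GeneScore]:
    """Regress confounders out of -log10(best p) and re-express as p-values.

    Parameters
    ----------
    raw:
        Triples ``(gene_id, best_p, covariate dict)``; the dict may carry
        extra user-supplied columns (e.g. LD-based covariates).
    covariates:
        Which covariate names to offer to the stepwise selection;
        defaults to gene size (kb), SNP count and SNPs per kb.

    Returns
    -------
    One :class:`GeneScore` per input gene with ``corrected_p`` set to the
    empirical rank transform ``rank(-residual)/(N+1)`` — the gene with the
    largest positive residual (more signal than its covariates predict) is
    most significant.  Ties are broken by raw best p, then gene id, so the
    output is deterministic.
    """
    rows = [(g, float(p), dict(cov)) for g, p, cov in raw]
    n = len(rows)
    if n < MIN_GENES_FOR_CORRECTION:
        raise ValueError(
            f"confounder correction needs >= {MIN_GENES_FOR_CORRECTION} genes, got {n}"
        )
    if covariates is None:
        covariates = DEFAULT_COVARIATES
    gene_ids = [g for g, _, _ in rows]
    best_p = np.array([p for _, p, _ in rows])
    y = -np.log10(best_p)

    X = pd.DataFrame(
        {name: [cov.get(name, np.nan) for _, _, cov in rows] for name in covariates}
    )
    usable = []
    for name in X.columns:
        col = X[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)):
            logger.warning("covariate %s has non-finite values; dropped", name)
        elif np.ptp(col) == 0:
            logger.info("covariate %s is constant; dropped", name)
        else:
            usable.append(name)
    X = X[usable]

    selected = _forward_stepwise(y, X) if usable else []
    if selected:
        design = sm.add_constant(X[selected].to_numpy(), has_constant="add")
        resid = sm.OLS(y, design).fit().resid
    else:
        resid = y - y.mean()

    # Most extreme residual -> rank 1 -> corrected_p = 1/(N+1).
    order = np.lexsort((gene_ids, best_p, -resid))
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    corrected = ranks / (n + 1)

    out = []
    for i, (gene_id, p, cov) in enumerate(rows):
        cp = float(corrected[i])
        out.append(
            GeneScore(
                gene_id=gene_id,
                best_snp_p=p,
                n_snps=int(cov.get("n_snps", 0)) or 0,
                covariates=cov,
                corrected_p=cp,
                neg_log10_p=-math.log10(cp),
            )
        )
    logger.info(
        "corrected %d gene scores; covariates entered: %s", n, selected or "none"
    )
    return out


def score_genes(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneAnnotation],
    window_bp: int = 10_000,
    covariates: Sequence[str] | None = None,
) -> list[GeneScore]:
    """Full gene scoring: assign SNPs, take best p, correct for confounders."""
    assigned = assign_snps_to_genes(snps, genes, window_bp=window_bp)
    best = best_snp_pvalue(assigned)
    gene_len = {g.gene_id: (g.end - g.start + 1) / 1000.0 for g in genes}
    raw = []
    best_ids = {}
    for gene_id, (p, n_snps, snp_id) in best.items():
        size_kb = gene_len[gene_id]
        raw.append(
            (
                gene_id,
                p,
                {
                    "gene_size_kb": size_kb,
                    "n_snps": float(n_snps),
                    "snps_per_kb": n_snps / size_kb,
                },
            )
        )
        best_ids[gene_id] = snp_id
    scores = correct_gene_scores(raw, covariates=covariates)
    return [
        GeneScore(
            gene_id=s.gene_id,
            best_snp_p=s.best_snp_p,
            n_snps=int(s.covariates["n_snps"]),
            covariates=s.covariates,
            corrected_p=s.corrected_p,
            neg_log10_p=s.neg_log10_p,
            best_snp_id=best_ids[s.gene_id],
        )
        for s in scores
    ]


def scores_to_frame(scores: Sequence[GeneScore]) -> pd.DataFrame:
    """Tabulate gene scores (one row per gene) for TSV output."""
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in scores],
            "best_snp_p": [s.best_snp_p for s in scores],
            "best_snp_id": [s.best_snp_id for s in scores],
            "n_snps": [s.n_snps for s in scores],
            "gene_size_kb": [s.covariates.get("gene_size_kb") for s in scores],
            "snps_per_kb": [s.covariates.get("snps_per_kb") for s in scores],
            "corrected_p": [s.corrected_p for s in scores],
            "neg_log10_p": [s.neg_log10_p for s in scores],
        }
    ).sort_values("corrected_p", kind="mergesort", ignore_index=True)
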