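"""Reproducibility/specificity scoring of primary-LCC proteins.

Each protein of the primary dataset's LCC starts at 0.5.  Presence in
the replication dataset's LCC adds 0.5; presence in each of K unrelated
disease LCCs subtracts 0.5/K (K = 6 in the classical design).  Scores
therefore live on an exact lattice in [0, 1]: 1 means "replicated and
disease-specific", 0 means "not replicated and present in every
unrelated-disease network".

Arithmetic uses exact rationals internally (0.5/6 does not terminate in
binary), so score equality tests are exact; reported values are rounded
to four decimals only at output.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "SpecificityScore",
    "score_proteins",
    "score_summary",
    "top_gene_network",
]


@dataclass(frozen=True)
class SpecificityScore:
    """Score of one primary-LCC protein with its presence flags."""

    protein_id: str
    in_replication_lcc: bool
    n_unrelated_lccs: int
    score_exact: Fraction

    @property
    def score(self) -> float:
        return float(self.score_exact)


def exact_score(in_replication: bool, n_unrelated: int, k_unrelated: int = 6) -> Fraction:
    """Base 1/2, plus 1/2 if replicated, minus (1/2)/K per unrelated presence."""
    if not 0 <= n_unrelated <= k_unrelated:
        raise ValueError(
            f"n_unrelated must be in [0, {k_unrelated}], got {n_unrelated}"
        )
    return (
        Fraction(1, 2)
        + (Fraction(1, 2) if in_replication else 0)
        - Fraction(1, 2) * Fraction(n_unrelated, k_unrelated)
    )


def score_proteins(
    primary_lcc: Iterable[str],
    replication_lcc: Iterable[str],
    unrelated_lccs: Sequence[Iterable[str]],
) -> list[SpecificityScore]:
    """Score every primary-LCC protein for reproducibility and specificity.

    Parameters
    ----------
    primary_lcc:
        Proteins of the discovery dataset's LCC (the set being ranked).
    replication_lcc:
        Proteins of the replication dataset's LCC.
    unrelated_lccs:
        One protein set per unrelated-disease dataset (K >= 1); the
        subtracted unit is 0.5/K so the endpoints 0 and 1 hold for any K.

    Returns scores sorted by descending score, then protein id.
    """
    primary = set(map(str, primary_lcc))
    if not primary:
        raise ValueError("primary LCC is empty")
    if len(unrelated_lccs) < 1:
        raise ValueError("at least one unrelated-disease LCC is required")
    replication = set(map(str, replication_lcc))
    unrelated = [set(map(str, s)) for s in unrelated_lccs]
    k = len(unrelated)
    out = []
    for p in primary:
        n_unrel = sum(p in s for s in unrelated)
        in_rep = p in replication
        out.append(
            SpecificityScore(
                protein_id=p,
                in_replication_lcc=in_rep,
                n_unrelated_lccs=n_unrel,
                score_exact=exact_score(in_rep, n_unrel, k),
            )
        )
    out.sort(key=lambda s: (-s.score_exact, s.protein_id))
    return out


def score_summary(scores: Sequence[SpecificityScore]) -> pd.DataFrame:
    """Counts and fractions by (replication, unrelated-count) stratum.

    The full strata table lets any marginal (e.g. "present only in the
    primary network") be read off directly.
    """
    if not scores:
        raise ValueError("no scores to summarize")
    rows: dict[tuple[bool, int], int] = {}
    for s in scores:
        key = (s.in_replication_lcc, s.n_unrelated_lccs)
        rows[key] = rows.get(key, 0) + 1
    n = len(scores)
    k = _infer_k(scores)
    records = []
    for (in_rep, n_unrel), count in sorted(rows.items(), key=lambda kv: kv[0]):
        records.append(
            {
                "in_replication_lcc": in_rep,
                "n_unrelated_lccs": n_unrel,
                "score": round(float(exact_score(in_rep, n_unrel, k)), 4),
                "count": count,
                "fraction": count / n,
            }
        )
    return pd.DataFrame(records)


def _infer_k(scores: Sequence[SpecificityScore]) -> int:
    # Recover K from the exact lattice: denominator of the subtracted unit.
    for s in scores:
        if s.n_unrelated_lccs:
            unit = Fraction(1, 2) + (Fraction(1, 2) if s.in_replication_lcc else 0) \
                - s.score_exact
            return int(Fraction(s.n_unrelated_lccs, 2) / unit)
    return 6


def top_gene_network(
    primary_lcc_graph: nx.Graph,
    scores: Sequence[SpecificityScore],
    score_threshold: float = 1.0,
) -> nx.Graph:
    """Subnetwork of top-scoring proteins and their first neighbors in the LCC.

    Nodes are the proteins scoring at least ``score_threshold`` plus all
    their direct neighbors within the LCC-induced graph; edges are
    induced.  Each node carries a ``score`` attribute (for map coloring);
    neighbors without a score (never in the primary LCC) are impossible
    by construction.
    """
    by_id = {s.protein_id: s for s in scores}
    missing = set(by_id) - set(primary_lcc_graph.nodes)
    if missing:
        raise ValueError(
            f"{len(missing)} scored proteins absent from the LCC graph"
        )
    top = {p for p, s in by_id.items() if s.score >= score_threshold}
    if not top:
        raise ValueError(
            f"no protein scores >= {score_threshold}; lower the threshold"
        )
    nodes = set(top)
    for p in top:
        nodes |= set(primary_lcc_graph.neighbors(p))
    sub = primary_lcc_graph.subgraph(nodes).copy()
    for p in sub.nodes:
        if p in by_id:
            sub.nodes[p]["score"] = float(by_id[p].score_exact)
            sub.nodes[p]["is_top"] = p in top
    return sub


def scores_to_frame(scores: Sequence[SpecificityScore]) -> pd.DataFrame:
    """Tabulate specificity scores for TSV output (scores to 4 decimals)."""
    return pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in scores],
            "in_replication_lcc": [s.in_replication_lcc for s in scores],
            "n_unrelated_lccs": [s.n_unrelated_lccs for s in scores],
            "score": [round(float(s.score_exact), 4) for s in scores],
        }
    )
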