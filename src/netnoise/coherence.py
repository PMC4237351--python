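"""Functional-coherence statistics of a selected protein set versus random sets.

True disease proteins tend to interact directly and to coalesce into a
large connected component, while statistical noise scatters over the
network.  Three metrics capture this at each gene-wise significance
cutoff:

1. percentage of selected proteins with at least one edge to another
   selected protein (``pct_direct``);
2. percentage of isolated nodes — selected proteins with no edge to any
   other selected protein (``pct_isolated``, the complement of 1);
3. the size of the largest connected component of the induced subgraph
   (``lcc_size``).

Because "proteins directly interacting" can also be read as a pairwise
quantity, the within-set edge density (edges / C(n,2)) is computed and
tested alongside.

Significance is empirical: each observed metric is compared with the same
metric on ``n_perm`` equal-size sets of randomly selected network
proteins, using the add-one estimator ``(1 + r)/(n_perm + 1)`` (never
zero; the floor at the default 1000 permutations is 1/1001).  Ties count
as extreme, which is conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np

from .network import AdjacencyIndex, SelectedSet, map_to_network, select_genes
from .scoring import GeneScore

logger = logging.getLogger(__name__)

__all__ = [
    "TopologyMetrics",
    "CoherenceResult",
    "METRIC_DIRECTIONS",
    "topology_metrics",
    "random_null",
    "empirical_p",
    "coherence_scan",
    "scan_to_frame",
    "default_cutoff_grid",
]

#: Direction in which each metric signals coherence beyond chance.
METRIC_DIRECTIONS: Mapping[str, str] = {
    "pct_direct": "greater",
    "edge_density": "greater",
    "pct_isolated": "smaller",
    "lcc_size": "greater",
}


def default_cutoff_grid() -> list[float]:
    """The standard -log10 p scan grid, 0.5 to 5.0 in steps of 0.5."""
    return [round(0.5 * k, 1) for k in range(1, 11)]


@dataclass(frozen=True)
class TopologyMetrics:
    """Coherence metrics of one protein set on the network."""

    n_selected: int
    pct_direct: float
    edge_density: float
    pct_isolated: float
    lcc_size: int

    def as_dict(self) -> dict[str, float]:
        return {
            "pct_direct": self.pct_direct,
            "edge_density": self.edge_density,
            "pct_isolated": self.pct_isolated,
            "lcc_size": float(self.lcc_size),
        }


@dataclass
class CoherenceResult:
    """Observed metrics, null distributions and empirical p at one cutoff."""

    cutoff_neglogp: float
    observed: TopologyMetrics
    null_samples: dict[str, np.ndarray]
    empirical_p: dict[str, float]
    selected: SelectedSet | None = None


def _metrics_from_degrees_and_components(
    n: int, within_deg: np.ndarray, comp_sizes: np.ndarray
) -> TopologyMetrics:
    if n == 0:
        return TopologyMetrics(0, 0.0, 0.0, 0.0, 0)
    n_isolated = int(np.count_nonzero(within_deg == 0))
    n_edges = int(within_deg.sum()) // 2
    n_pairs = n * (n - 1) // 2
    return TopologyMetrics(
        n_selected=n,
        pct_direct=100.0 * (n - n_isolated) / n,
        edge_density=(n_edges / n_pairs) if n_pairs else 0.0,
        pct_isolated=100.0 * n_isolated / n,
        lcc_size=int(comp_sizes[0]) if comp_sizes.size else min(n, 1),
    )


def _metrics_at(index: AdjacencyIndex, idx: np.ndarray) -> TopologyMetrics:
    return _metrics_from_degrees_and_components(
        idx.size, index.within_degrees(idx), index.component_sizes(idx)
    )


def topology_metrics(
    net: nx.Graph | AdjacencyIndex, subset: Iterable[str]
) -> TopologyMetrics:
    """Compute the coherence metrics for one selected protein set.

    An empty subset yields all-zero metrics (with a warning), so scans can
    run past the cutoff where the selection empties.
    """
    index = net if isinstance(net, AdjacencyIndex) else AdjacencyIndex(net)
    subset = set(subset)
    if not subset:
        logger.warning("topology_metrics called on an empty subset")
        return TopologyMetrics(0, 0.0, 0.0, 0.0, 0)
    if not subset <= set(index.nodes):
        raise ValueError("subset contains nodes absent from the network")
    return _metrics_at(index, index.indices_of(subset))


def random_null(
    net: nx.Graph | AdjacencyIndex,
    set_size: int,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    mode: Literal["uniform", "degree_matched"] = "uniform",
    match_set: Iterable[str] | None = None,
    universe: Iterable[str] | None = None,
) -> dict[str, np.ndarray]:
    """Null distributions of the metrics over random equal-size protein sets.

    Parameters
    ----------
    set_size:
        Size of each random set (the observed selection size).
    mode:
        ``uniform`` draws nodes uniformly without replacement from the
        universe (the default, and the classical null).  ``degree_matched``
        bins universe nodes into degree deciles and draws, within each
        bin, as many nodes as the observed set (``match_set``) has there —
        a robustness variant for degree-driven selections.
    universe:
        Node pool to sample from; defaults to all network nodes.

    Returns
    -------
    Mapping from metric name to an array of length ``n_perm``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    index = net if isinstance(net, AdjacencyIndex) else AdjacencyIndex(net)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if universe is None:
        pool = np.arange(len(index), dtype=np.int64)
    else:
        pool = index.indices_of(set(universe))
    if set_size > pool.size:
        raise ValueError(
            f"set_size {set_size} exceeds the {pool.size}-node sampling universe"
        )

    if mode == "degree_matched":
        if match_set is None:
            raise ValueError("degree_matched mode requires match_set")
        degrees = np.asarray(self_degrees(index), dtype=np.int64)
        edges = np.quantile(degrees[pool], np.linspace(0, 1, 11))
        bin_of = np.searchsorted(edges[1:-1], degrees, side="right")
        obs_idx = index.indices_of(set(match_set))
        bins = [pool[bin_of[pool] == b] for b in range(10)]
        wanted = np.bincount(bin_of[obs_idx], minlength=10)
        for b, (have, want) in enumerate(zip(bins, wanted)):
            if want > have.size:
                raise ValueError(f"degree bin {b} too small to match observed set")

    samples: dict[str, list[float]] = {m: [] for m in METRIC_DIRECTIONS}
    for _ in range(n_perm):
        if mode == "uniform":
            idx = rng.choice(pool, size=set_size, replace=False)
        elif mode == "degree_matched":
            parts = [
                rng.choice(bins[b], size=int(wanted[b]), replace=False)
                for b in range(10)
                if wanted[b]
            ]
            idx = np.concatenate(parts) if parts else np.zeros(0, dtype=np.int64)
        else:
            raise ValueError(f"unknown null mode {mode!r}")
        m = _metrics_at(index, idx)
        for name, value in m.as_dict().items():
            samples[name].append(value)
    return {name: np.asarray(vals) for name, vals in samples.items()}


def self_degrees(index: AdjacencyIndex) -> np.ndarray:
    """Degree of every node in fixed node order."""
    return np.asarray(index.adj.sum(axis=1)).ravel()


def empirical_p(
    observed: float,
    null: np.ndarray | Sequence[float],
    direction: Literal["greater", "smaller"] = "greater",
) -> float:
    """Add-one empirical p-value of an observed metric against its null.

    ``(1 + #{null as or more extreme}) / (n + 1)``; ties count as extreme,
    and the result is always in (0, 1] with floor ``1/(n+1)``.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    if direction == "greater":
        r = int(np.count_nonzero(null >= observed))
    elif direction == "smaller":
        r = int(np.count_nonzero(null <= observed))
    else:
        raise ValueError(f"direction must be 'greater' or 'smaller', got {direction!r}")
    return (1 + r) / (null.size + 1)


def coherence_scan(
    scores: Sequence[GeneScore],
    gene_protein_map: Iterable[tuple[str, str]],
    net: nx.Graph | AdjacencyIndex,
    cutoffs: Sequence[float] | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    mode: Literal["uniform", "degree_matched"] = "uniform",
    null_universe: Literal["network", "mapped"] = "network",
) -> list[CoherenceResult]:
    """Coherence metrics and empirical p-values over a cutoff scan.

    One :class:`CoherenceResult` per cutoff (ascending); the scan stops
    at the first cutoff whose selection maps to an empty protein set.
    Null set sizes always equal the selected-set size at that cutoff.
    ``null_universe="mapped"`` restricts the random pool to proteins
    reachable from scored genes through the id map.
    """
    index = net if isinstance(net, AdjacencyIndex) else AdjacencyIndex(net)
    if cutoffs is None:
        cutoffs = default_cutoff_grid()
    cutoffs = list(cutoffs)
    if sorted(cutoffs) != cutoffs:
        raise ValueError("cutoffs must be sorted ascending")
    gp = list(gene_protein_map)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    universe = None
    if null_universe == "mapped":
        scored = {s.gene_id for s in scores}
        universe = {p for g, p in gp if g in scored and p in index.index}

    results: list[CoherenceResult] = []
    for cutoff in cutoffs:
        genes = select_genes(scores, cutoff)
        selected = map_to_network(genes, gp, index_graph(index), cutoff_neglogp=cutoff)
        if not selected.proteins:
            logger.info("scan stops at cutoff %.3g: empty protein set", cutoff)
            break
        observed = topology_metrics(index, selected.proteins)
        null = random_null(
            index,
            set_size=len(selected.proteins),
            n_perm=n_perm,
            seed=rng,
            mode=mode,
            match_set=selected.proteins if mode == "degree_matched" else None,
            universe=universe,
        )
        pvals = {
            name: empirical_p(observed.as_dict()[name], null[name], direction)
            for name, direction in METRIC_DIRECTIONS.items()
        }
        results.append(
            CoherenceResult(
                cutoff_neglogp=cutoff,
                observed=observed,
                null_samples=null,
                empirical_p=pvals,
                selected=selected,
            )
        )
    return results


class _GraphView:
    """Minimal node-set view over an AdjacencyIndex for map_to_network."""

    def __init__(self, index: AdjacencyIndex):
        self.nodes = index.nodes


def index_graph(index: AdjacencyIndex) -> "_GraphView":
    return _GraphView(index)


def scan_to_frame(results: Sequence[CoherenceResult]):
    """Flatten a scan into a table: observed, null summaries, empirical p."""
    import pandas as pd

    rows = []
    for res in results:
        row: dict[str, float] = {
            "cutoff_neglogp": res.cutoff_neglogp,
            "n_selected": res.observed.n_selected,
        }
        for name, obs in res.observed.as_dict().items():
            null = res.null_samples[name]
            row[f"{name}_observed"] = obs
            row[f"{name}_null_mean"] = float(null.mean())
            row[f"{name}_null_sd"] = float(null.std(ddof=1)) if null.size > 1 else 0.0
            row[f"{name}_null_q25"] = float(np.quantile(null, 0.25))
            row[f"{name}_null_q75"] = float(np.quantile(null, 0.75))
            row[f"{name}_empirical_p"] = res.empirical_p[name]
        rows.append(row)
    return pd.DataFrame(rows)


def plot_scan(results: Sequence[CoherenceResult], path: str | None = None):
    """Three-panel scan figure: % direct, % isolated, log10 LCC size.

    Observed values as a red line, null mean as a blue line with the
    interquartile band shaded.  Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cutoffs = [r.cutoff_neglogp for r in results]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    panels = [
        ("pct_direct", "% direct interactions", lambda v: v),
        ("pct_isolated", "% isolated nodes", lambda v: v),
        ("lcc_size", "log10 LCC size", lambda v: np.log10(np.maximum(v, 1))),
    ]
    for ax, (metric, label, tf) in zip(axes, panels):
        obs = [tf(r.observed.as_dict()[metric]) for r in results]
        mean = [tf(r.null_samples[metric]).mean() for r in results]
        lo = [np.quantile(tf(r.null_samples[metric]), 0.25) for r in results]
        hi = [np.quantile(tf(r.null_samples[metric]), 0.75) for r in results]
        ax.fill_between(cutoffs, lo, hi, color="0.8", label="null IQR")
        ax.plot(cutoffs, mean, color="tab:blue", label="null mean")
        ax.plot(cutoffs, obs, color="tab:red", marker="o", label="observed")
        ax.set_xlabel("-log10 gene-wise P cutoff")
        ax.set_ylabel(label)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
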