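"""Model-level interface: build a study from data, fit, inspect results.

:class:`NetworkGwas` holds one study's data — per-SNP association
results, gene annotation, the PPI network, the gene↔protein map and
optionally a candidate gene list.  :meth:`NetworkGwas.fit` runs the
pipeline (gene scoring → network projection → coherence scan → LCC
extraction → candidate benchmarking) and returns a
:class:`NetworkGwasResults` carrying the estimates, null distributions,
empirical p-values and a ``summary()`` table.  Cross-dataset overlap and
specificity scoring operate on pairs / collections of fitted results.

``run_all`` is the orchestrated, file-based entry point used by the CLI:
it reads a YAML config, executes the workflow and writes every output
TSV plus a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from . import io as nio
from .coherence import (
    CoherenceResult,
    coherence_scan,
    scan_to_frame,
)
from .evaluation import (
    EvaluationResult,
    OverlapResult,
    build_selections,
    cross_dataset_overlap,
    precision_recall,
)
from .network import AdjacencyIndex, connected_components, map_to_network, select_genes
from .scoring import GeneScore, score_genes, scores_to_frame
from .simulate import SyntheticDataset
from .specificity import SpecificityScore, score_proteins

__all__ = [
    "NetworkGwas",
    "NetworkGwasResults",
    "overlap_between",
    "specificity_between",
    "run_all",
]

#: Metrics that must beat chance for the auto-selected cutoff.
_PRIMARY_METRICS = ("pct_direct", "pct_isolated", "lcc_size")


class NetworkGwas:
    """A GWAS dataset superimposed on a protein-protein interaction network.

    Parameters
    ----------
    snps:
        Per-SNP association records (id, chromosome, position, p-value).
    genes:
        Gene bodies, 1-based inclusive coordinates.
    network:
        Undirected simple PPI graph.
    gene_protein_map:
        ``(gene_id, protein_id)`` pairs.
    candidates:
        Optional known-candidate gene list for benchmarking.
    window_bp:
        SNP→gene assignment window on each side of the gene body.
    """

    def __init__(
        self,
        snps: Sequence[nio.SnpRecord],
        genes: Sequence[nio.GeneAnnotation],
        network: nx.Graph,
        gene_protein_map: Sequence[tuple[str, str]],
        candidates: set[str] | None = None,
        window_bp: int = 10_000,
        covariates: Sequence[str] | None = None,
        label: str = "dataset",
    ):
        self.snps = list(snps)
        self.genes = list(genes)
        self.network = network
        self.gene_protein_map = list(gene_protein_map)
        self.candidates = set(candidates) if candidates else None
        self.window_bp = int(window_bp)
        self.covariates = covariates
        self.label = label
        self._index: AdjacencyIndex | None = None

    @property
    def adjacency(self) -> AdjacencyIndex:
        if self._index is None:
            self._index = AdjacencyIndex(self.network)
        return self._index

    @classmethod
    def from_files(
        cls,
        association: str | Path,
        genes: str | Path,
        network: str | Path,
        gene_protein_map: str | Path,
        candidates: str | Path | None = None,
        assoc_columns: Mapping[str, str] | None = None,
        gene_dialect: str = "tsv1",
        window_bp: int = 10_000,
        label: str | None = None,
    ) -> "NetworkGwas":
        """Build a model from the standard on-disk formats."""
        snps, _ = nio.read_association_table(association, assoc_columns)
        gene_ann, _ = nio.read_gene_annotation(genes, dialect=gene_dialect)
        net, _ = nio.read_edge_list(network)
        gp, _ = nio.read_gene_protein_map(gene_protein_map)
        cand = None
        if candidates is not None:
            cand, _ = nio.read_gene_list(candidates)
        return cls(
            snps, gene_ann, net, gp, candidates=cand, window_bp=window_bp,
            label=label or Path(association).stem,
        )

    @classmethod
    def from_synthetic(cls, ds: SyntheticDataset, label: str = "synthetic") -> "NetworkGwas":
        """Build a model directly from a generated study."""
        return cls(
            ds.snps, ds.genes, ds.network, ds.gene_protein_map,
            candidates=ds.candidates or None, window_bp=ds.config.window_bp,
            label=label,
        )

    def fit(
        self,
        cutoffs: Sequence[float] | None = None,
        lcc_cutoff: float | Literal["auto"] = 1.0,
        n_perm: int = 1000,
        seed: int | None = None,
        null_mode: Literal["uniform", "degree_matched"] = "uniform",
        null_universe: Literal["network", "mapped"] = "network",
        alpha: float = 0.05,
    ) -> "NetworkGwasResults":
        """Run scoring, the coherence scan and LCC extraction.

        ``lcc_cutoff`` fixes the -log10 p threshold at which the LCC is
        extracted; ``"auto"`` picks the smallest scanned cutoff where all
        three coherence metrics beat chance at ``alpha``.
        """
        scores = score_genes(
            self.snps, self.genes, window_bp=self.window_bp,
            covariates=self.covariates,
        )
        index = self.adjacency
        scan = coherence_scan(
            scores, self.gene_protein_map, index,
            cutoffs=cutoffs, n_perm=n_perm, seed=seed,
            mode=null_mode, null_universe=null_universe,
        )
        if lcc_cutoff == "auto":
            chosen = None
            for res in scan:
                if all(res.empirical_p[m] < alpha for m in _PRIMARY_METRICS):
                    chosen = res.cutoff_neglogp
                    break
            if chosen is None:
                raise ValueError(
                    f"no scanned cutoff has all coherence metrics significant "
                    f"at alpha={alpha}; pass an explicit lcc_cutoff"
                )
            lcc_cutoff = chosen

        selected_genes = select_genes(scores, lcc_cutoff)
        selected = map_to_network(
            selected_genes, self.gene_protein_map, self.network,
            cutoff_neglogp=lcc_cutoff,
        )
        components = connected_components(self.network, selected.proteins)
        lcc_proteins = components[0] if components else set()
        by_protein: dict[str, set[str]] = {}
        for g, p in self.gene_protein_map:
            if g in selected_genes:
                by_protein.setdefault(p, set()).add(g)
        lcc_genes = set().union(*(by_protein.get(p, set()) for p in lcc_proteins)) \
            if lcc_proteins else set()

        evaluations: list[EvaluationResult] = []
        selections: dict[str, set[str]] = {}
        if self.candidates and lcc_genes:
            selections = build_selections(scores, lcc_genes, lcc_cutoff)
            evaluations = [
                precision_recall(sel, self.candidates, selection_label=name)
                for name, sel in selections.items()
            ]
        return NetworkGwasResults(
            model=self,
            gene_scores=scores,
            scan=scan,
            lcc_cutoff=float(lcc_cutoff),
            selected=selected,
            components=components,
            lcc_proteins=lcc_proteins,
            lcc_genes=lcc_genes,
            selections=selections,
            evaluations=evaluations,
            n_perm=n_perm,
            seed=seed,
        )


class NetworkGwasResults:
    """Fitted pipeline outputs for one dataset."""

    def __init__(
        self,
        model: NetworkGwas,
        gene_scores: list[GeneScore],
        scan: list[CoherenceResult],
        lcc_cutoff: float,
        selected,
        components: list[set[str]],
        lcc_proteins: set[str],
        lcc_genes: set[str],
        selections: dict[str, set[str]],
        evaluations: list[EvaluationResult],
        n_perm: int,
        seed: int | None,
    ):
        self.model = model
        self.gene_scores = gene_scores
        self.scan = scan
        self.lcc_cutoff = lcc_cutoff
        self.selected = selected
        self.components = components
        self.lcc_proteins = lcc_proteins
        self.lcc_genes = lcc_genes
        self.selections = selections
        self.evaluations = evaluations
        self.n_perm = n_perm
        self.seed = seed

    # -- tabular views -------------------------------------------------
    @property
    def scores_frame(self) -> pd.DataFrame:
        return scores_to_frame(self.gene_scores)

    @property
    def scan_frame(self) -> pd.DataFrame:
        return scan_to_frame(self.scan)

    @property
    def components_frame(self) -> pd.DataFrame:
        rows = []
        gene_by_protein: dict[str, set[str]] = {}
        for g, p in self.model.gene_protein_map:
            if g in self.selected.genes:
                gene_by_protein.setdefault(p, set()).add(g)
        for i, comp in enumerate(self.components, start=1):
            genes = sorted(set().union(*(gene_by_protein.get(p, set()) for p in comp)))
            rows.append(
                {
                    "component_id": i,
                    "size": len(comp),
                    "proteins": ",".join(sorted(comp)),
                    "genes": ",".join(genes),
                }
            )
        return pd.DataFrame(rows)

    @property
    def evaluation_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(e) for e in self.evaluations])

    def lcc_graph(self) -> nx.Graph:
        """The subgraph induced by the LCC proteins."""
        return self.model.network.subgraph(self.lcc_proteins).copy()

    def plot_scan(self, path: str | None = None):
        from .coherence import plot_scan

        return plot_scan(self.scan, path)

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        """Plain-text report of the fitted pipeline."""
        m = self.model
        lines = [
            "Network-based GWAS coherence analysis",
            "=" * 64,
            f"dataset: {m.label}",
            f"SNPs: {len(m.snps)}   genes annotated: {len(m.genes)}   "
            f"genes scored: {len(self.gene_scores)}",
            f"network: {m.network.number_of_nodes()} proteins, "
            f"{m.network.number_of_edges()} interactions",
            f"assignment window: +/-{m.window_bp} bp   "
            f"permutations: {self.n_perm}   seed: {self.seed}",
            "",
            "Coherence scan (observed vs. equal-size random protein sets)",
            "-" * 64,
            f"{'cutoff':>6} {'n_sel':>6} {'%direct':>8} {'%isol':>7} "
            f"{'LCC':>5} {'p_direct':>9} {'p_isol':>8} {'p_lcc':>8}",
        ]
        for res in self.scan:
            o = res.observed
            lines.append(
                f"{res.cutoff_neglogp:>6.2f} {o.n_selected:>6d} "
                f"{o.pct_direct:>8.1f} {o.pct_isolated:>7.1f} {o.lcc_size:>5d} "
                f"{res.empirical_p['pct_direct']:>9.4f} "
                f"{res.empirical_p['pct_isolated']:>8.4f} "
                f"{res.empirical_p['lcc_size']:>8.4f}"
            )
        lines += [
            "-" * 64,
            f"LCC extracted at -log10 P = {self.lcc_cutoff:g}: "
            f"{len(self.lcc_proteins)} proteins / {len(self.lcc_genes)} genes "
            f"({len(self.components)} components, "
            f"{len(self.selected.proteins)} selected proteins)",
        ]
        if self.evaluations:
            lines += [
                "",
                "Candidate benchmark",
                "-" * 64,
                f"{'selection':>14} {'n':>6} {'hits':>5} "
                f"{'precision%':>11} {'recall%':>8}",
            ]
            for e in self.evaluations:
                lines.append(
                    f"{e.selection_label:>14} {e.n_selected:>6d} {e.n_hits:>5d} "
                    f"{e.precision_pct:>11.2f} {e.recall_pct:>8.2f}"
                )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write all tabular outputs under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gene_scores": outdir / "gene_scores.tsv",
            "scan": outdir / "coherence_scan.tsv",
            "components": outdir / "components.tsv",
            "lcc_genes": outdir / "lcc_genes.txt",
            "lcc_proteins": outdir / "lcc_proteins.txt",
            "summary": outdir / "summary.txt",
        }
        nio.write_tsv(self.scores_frame, paths["gene_scores"])
        nio.write_tsv(self.scan_frame, paths["scan"])
        nio.write_tsv(self.components_frame, paths["components"])
        nio.write_gene_list(self.lcc_genes, paths["lcc_genes"])
        nio.write_gene_list(self.lcc_proteins, paths["lcc_proteins"])
        paths["summary"].write_text(self.summary() + "\n")
        if self.evaluations:
            paths["evaluation"] = outdir / "evaluation.tsv"
            nio.write_tsv(self.evaluation_frame, paths["evaluation"])
        return paths


def overlap_between(
    res1: NetworkGwasResults, res2: NetworkGwasResults
) -> tuple[list[OverlapResult], Mapping[str, float]]:
    """SNP/gene/LCC-level Jaccard overlap between two fitted datasets."""
    return cross_dataset_overlap(
        res1.model.snps, res1.gene_scores, res1.lcc_genes,
        res2.model.snps, res2.gene_scores, res2.lcc_genes,
    )


def specificity_between(
    primary: NetworkGwasResults,
    replication: NetworkGwasResults,
    unrelated: Sequence[NetworkGwasResults],
) -> list[SpecificityScore]:
    """Specificity scores of the primary LCC proteins across fitted runs."""
    return score_proteins(
        primary.lcc_proteins,
        replication.lcc_proteins,
        [r.lcc_proteins for r in unrelated],
    )


# ---------------------------------------------------------------------------
# orchestrated, file-based workflow


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: Mapping | str | Path, outdir: str | Path | None = None) -> Path:
    """Execute the full workflow from a YAML config (or dict).

    Config keys: ``inputs`` (association/genes/network/map/candidates
    paths) or ``simulate`` (a synthetic-study parameter block), plus
    ``window_bp``, ``cutoffs``, ``lcc_cutoff`` (number or "auto"),
    ``n_perm``, ``seed``, ``outdir``.  Writes all stage outputs and a
    ``manifest.json`` that fully determines a bit-identical re-run.
    """
    import yaml

    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)
    out = Path(outdir or cfg.get("outdir", "netnoise_run"))
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seed = int(cfg.get("seed", 0))

    checksums = {}
    if "simulate" in cfg:
        from .simulate import SyntheticConfig, generate_dataset, write_dataset

        sim_cfg = SyntheticConfig.from_dict({**cfg["simulate"], "seed": seed})
        ds = generate_dataset(sim_cfg)
        sim_paths = write_dataset(ds, out / "simulated_input")
        checksums = {k: _sha256(p) for k, p in sim_paths.items()}
        model = NetworkGwas.from_synthetic(ds, label="simulated")
    elif "inputs" in cfg:
        inputs = cfg["inputs"]
        model = NetworkGwas.from_files(
            association=inputs["association"],
            genes=inputs["genes"],
            network=inputs["network"],
            gene_protein_map=inputs["map"],
            candidates=inputs.get("candidates"),
            assoc_columns=cfg.get("assoc_columns"),
            gene_dialect=cfg.get("gene_dialect", "tsv1"),
            window_bp=int(cfg.get("window_bp", 10_000)),
        )
        checksums = {
            k: _sha256(Path(v)) for k, v in inputs.items() if v is not None
        }
    else:
        raise ValueError("config needs an 'inputs' or a 'simulate' section")

    lcc_cutoff = cfg.get("lcc_cutoff", 1.0)
    if lcc_cutoff != "auto":
        lcc_cutoff = float(lcc_cutoff)
    results = model.fit(
        cutoffs=cfg.get("cutoffs"),
        lcc_cutoff=lcc_cutoff,
        n_perm=int(cfg.get("n_perm", 1000)),
        seed=seed,
        null_mode=cfg.get("null_mode", "uniform"),
        null_universe=cfg.get("null_universe", "network"),
    )
    results.save(out)

    manifest = {
        "package": "netnoise",
        "version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "seed": seed,
        "input_checksums": checksums,
        "counts": {
            "n_snps": len(model.snps),
            "n_genes_annotated": len(model.genes),
            "n_genes_scored": len(results.gene_scores),
            "n_network_proteins": model.network.number_of_nodes(),
            "n_network_edges": model.network.number_of_edges(),
            "n_selected_proteins": len(results.selected.proteins),
            "lcc_size": len(results.lcc_proteins),
            "lcc_cutoff": results.lcc_cutoff,
        },
        "started": t0,
        "elapsed_s": round(time.time() - t0, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out
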