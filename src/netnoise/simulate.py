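"""Synthetic GWAS + PPI data with a planted disease module.

The generator emulates the statistical structure the pipeline assumes:

* a sparse undirected background PPI network (Erdős–Rényi by default,
  Barabási–Albert optionally) with the mean degree of the 12372-protein
  reference compilation (~9.4), which keeps random cutoff-level
  selections of ~10% of the proteins near the percolation threshold of
  the induced subgraph — the regime where the largest-component test is
  most discriminating;
* a planted *disease module*: a connected set of proteins whose internal
  edge probability is boosted by a configurable factor;
* per-SNP association p-values that are Uniform(0, 1) off the module and
  Beta(b, 1) with b < 1 for SNPs in signal-carrying module genes —
  the canonical one-parameter enrichment of small p-values, with the
  closed-form CDF P(p <= x) = x**b that analytic test oracles use;
* a 1:1 gene↔protein map by construction, and a candidate gene list with
  a controlled overlap with the module.

Gene bodies are laid out non-overlapping with intergenic gaps wider than
twice the SNP-assignment window, so SNP→gene assignment is exactly
checkable; intergenic SNPs fall outside every gene window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import yaml

from .io import GeneAnnotation, SnpRecord, write_gene_list, write_tsv

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "make_network",
    "make_association",
    "make_candidates",
    "generate_dataset",
    "generate_pair",
    "write_dataset",
]

#: Mean degree of the compiled human PPI network this emulates
#: (58365 interactions over 12372 proteins).
REFERENCE_MEAN_DEGREE = 2 * 58365 / 12372

_P_FLOOR = 1e-300  # keep simulated p-values strictly positive


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic study.

    Defaults are desk-scale study conditions: a 2000-protein network with
    realistic sparsity, a 60-protein planted module with five-fold edge
    enrichment, 3000 genes with ~10 SNPs each, strong sub-threshold
    signal (Beta(0.2, 1)) in 80% of module genes, and a candidate list
    half-overlapping the module.
    """

    n_proteins: int = 2000
    edge_model: str = "erdos_renyi"  # or "barabasi_albert"
    edge_p: float | None = None  # ER edge probability; None -> from mean_degree
    mean_degree: float = REFERENCE_MEAN_DEGREE
    ba_m: int = 5  # BA attachment parameter
    module_size: int = 60
    module_edge_boost: float = 5.0
    n_genes: int = 3000
    snps_per_gene: tuple[int, int] = (5, 15)
    n_intergenic_snps: int = 20000
    gene_length_bp: tuple[int, int] = (2_000, 50_000)
    genes_per_chrom: int = 150
    window_bp: int = 10_000
    signal_fraction: float = 0.8
    signal_beta: float = 0.2
    candidate_overlap: float = 0.5
    n_candidates: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.module_size <= self.n_proteins:
            raise ValueError("module_size must be in [1, n_proteins]")
        if self.n_proteins > self.n_genes:
            raise ValueError("need n_genes >= n_proteins for a 1:1 map")
        if not 0 <= self.signal_fraction <= 1:
            raise ValueError("signal_fraction must be in [0, 1]")
        if not 0 <= self.candidate_overlap <= 1:
            raise ValueError("candidate_overlap must be in [0, 1]")
        if self.signal_beta <= 0:
            raise ValueError("signal_beta must be > 0")
        if self.module_edge_boost < 1:
            raise ValueError("module_edge_boost must be >= 1")

    @property
    def background_edge_p(self) -> float:
        if self.edge_p is not None:
            return self.edge_p
        return self.mean_degree / (self.n_proteins - 1)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("snps_per_gene", "gene_length_bp"):
            if key in d and isinstance(d[key], (list, tuple)):
                d[key] = tuple(int(v) for v in d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["snps_per_gene"] = list(self.snps_per_gene)
        d["gene_length_bp"] = list(self.gene_length_bp)
        return d


@dataclass
class SyntheticDataset:
    """One generated study: network, association data, map, truth labels."""

    config: SyntheticConfig
    network: nx.Graph
    module_proteins: list[str]
    snps: list[SnpRecord]
    genes: list[GeneAnnotation]
    gene_protein_map: list[tuple[str, str]]
    module_genes: list[str]
    signal_genes: set[str]
    candidates: set[str] = field(default_factory=set)


def _protein_id(i: int) -> str:
    return f"P{i:05d}"


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def make_network(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[nx.Graph, list[str]]:
    """Background network plus a connected planted module.

    Module-internal edges are resampled at ``boost × background p``
    (capped at 1; a huge boost yields a clique).  If resampling does not
    produce a connected module within a bounded number of retries —
    which it cannot at realistic sparsity — the remaining module
    components are joined by random inter-component edges, so the
    planted module is connected by construction.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_proteins
    p_bg = cfg.background_edge_p
    if cfg.edge_model == "erdos_renyi":
        if not 0 < p_bg <= 1:
            raise ValueError(f"background edge probability {p_bg} outside (0, 1]")
        g = nx.fast_gnp_random_graph(n, p_bg, seed=int(rng.integers(2**31)))
    elif cfg.edge_model == "barabasi_albert":
        g = nx.barabasi_albert_graph(n, cfg.ba_m, seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown edge_model {cfg.edge_model!r}")

    density = 2 * g.number_of_edges() / (n * (n - 1))
    p_in = min(1.0, cfg.module_edge_boost * density)
    module = sorted(rng.choice(n, size=cfg.module_size, replace=False).tolist())

    for _retry in range(20):
        # resample all module-internal pairs at the boosted probability
        for i, u in enumerate(module):
            for v in module[i + 1:]:
                if g.has_edge(u, v):
                    g.remove_edge(u, v)
        m = len(module)
        if m > 1:
            tri = np.triu_indices(m, k=1)
            draw = rng.random(tri[0].size) < p_in
            for a, b in zip(tri[0][draw], tri[1][draw]):
                g.add_edge(module[a], module[b])
        if nx.is_connected(g.subgraph(module)):
            break
    else:
        comps = [sorted(c) for c in nx.connected_components(g.subgraph(module))]
        comps.sort(key=len, reverse=True)
        core = comps[0]
        for comp in comps[1:]:
            u = comp[int(rng.integers(len(comp)))]
            v = core[int(rng.integers(len(core)))]
            g.add_edge(u, v)
            core = core + comp
        assert nx.is_connected(g.subgraph(module))

    mapping = {i: _protein_id(i) for i in g.nodes}
    return nx.relabel_nodes(g, mapping), [_protein_id(i) for i in module]


def _layout_genes(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> list[GeneAnnotation]:
    """Non-overlapping gene bodies with gaps wider than twice the window."""
    genes: list[GeneAnnotation] = []
    lo, hi = cfg.gene_length_bp
    min_gap = 2 * cfg.window_bp + 5_000
    for i in range(cfg.n_genes):
        chrom = str(i // cfg.genes_per_chrom + 1)
        if i % cfg.genes_per_chrom == 0:
            cursor = 1
        start = cursor + min_gap + int(rng.integers(0, 20_000))
        length = int(rng.integers(lo, hi + 1))
        genes.append(GeneAnnotation(_gene_id(i), chrom, start, start + length - 1))
        cursor = start + length - 1
    return genes


def make_association(
    cfg: SyntheticConfig,
    module_genes: Sequence[str],
    rng: np.random.Generator,
    genes: list[GeneAnnotation] | None = None,
) -> tuple[list[SnpRecord], list[GeneAnnotation], set[str]]:
    """SNP table over a synthetic gene layout, with signal in module genes.

    SNPs inside signal genes draw p ~ Beta(b, 1); all other SNPs
    (including intergenic ones, placed farther than the window from any
    gene) draw p ~ Uniform(0, 1).  Returns the SNP records, the gene
    annotation, and the set of signal-carrying genes.
    """
    if genes is None:
        genes = _layout_genes(cfg, rng)
    module_genes = list(module_genes)
    n_signal = int(round(cfg.signal_fraction * len(module_genes)))
    signal_genes = set(
        rng.choice(module_genes, size=n_signal, replace=False).tolist()
    ) if n_signal else set()

    snps: list[SnpRecord] = []
    counter = 0
    lo, hi = cfg.snps_per_gene
    for gene in genes:
        k = int(rng.integers(lo, hi + 1))
        span = gene.end - gene.start + 1
        offsets = rng.choice(span, size=min(k, span), replace=False)
        if gene.gene_id in signal_genes:
            pvals = rng.beta(cfg.signal_beta, 1.0, size=offsets.size)
        else:
            pvals = rng.uniform(0.0, 1.0, size=offsets.size)
        pvals = np.clip(pvals, _P_FLOOR, 1.0)
        for off, p in zip(np.sort(offsets), pvals):
            snps.append(
                SnpRecord(
                    snp_id=f"rs{counter:07d}",
                    chrom=gene.chrom,
                    pos=gene.start + int(off),
                    pvalue=float(p),
                )
            )
            counter += 1

    # intergenic SNPs: in gaps, strictly outside every gene's window
    gaps: list[tuple[str, int, int]] = []
    prev_end: dict[str, int] = {}
    for gene in genes:
        left = prev_end.get(gene.chrom, 0) + cfg.window_bp + 1
        right = gene.start - cfg.window_bp - 1
        if right >= left:
            gaps.append((gene.chrom, left, right))
        prev_end[gene.chrom] = gene.end
    if cfg.n_intergenic_snps and gaps:
        lengths = np.array([hi - lo + 1 for _, lo, hi in gaps], dtype=float)
        choice = rng.choice(len(gaps), size=cfg.n_intergenic_snps,
                            p=lengths / lengths.sum())
        pvals = np.clip(rng.uniform(0, 1, size=cfg.n_intergenic_snps), _P_FLOOR, 1.0)
        for gi, p in zip(choice, pvals):
            chrom, glo, ghi = gaps[int(gi)]
            snps.append(
                SnpRecord(
                    snp_id=f"rs{counter:07d}",
                    chrom=chrom,
                    pos=int(rng.integers(glo, ghi + 1)),
                    pvalue=float(p),
                )
            )
            counter += 1
    return snps, genes, signal_genes


def make_candidates(
    module_genes: Sequence[str],
    cfg: SyntheticConfig,
    all_genes: Sequence[str],
    rng: np.random.Generator,
) -> set[str]:
    """Candidate list with a controlled fraction drawn from the module."""
    n_module = int(round(cfg.candidate_overlap * cfg.n_candidates))
    if n_module > len(module_genes):
        raise ValueError(
            f"candidate_overlap requires {n_module} module genes, "
            f"module has {len(module_genes)}"
        )
    non_module = sorted(set(all_genes) - set(module_genes))
    n_other = cfg.n_candidates - n_module
    if n_other > len(non_module):
        raise ValueError("not enough non-module genes for the candidate list")
    cand = set(rng.choice(sorted(module_genes), size=n_module, replace=False).tolist())
    cand |= set(rng.choice(non_module, size=n_other, replace=False).tolist())
    return cand


def generate_dataset(
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticDataset:
    """Generate a full study: network, layout, SNPs, map, candidates.

    Fully deterministic given ``cfg.seed`` (or the supplied generator).
    Genes are mapped 1:1 to proteins (module proteins to module genes);
    genes beyond ``n_proteins`` have no protein and exercise the
    unmapped-gene path downstream.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    network, module_proteins = make_network(cfg, rng)

    # 1:1 map: pick a random gene for each protein; module proteins first
    gene_ids = [_gene_id(i) for i in range(cfg.n_genes)]
    shuffled = list(rng.permutation(gene_ids))
    module_genes = shuffled[: len(module_proteins)]
    other_proteins = sorted(set(network.nodes) - set(module_proteins))
    other_genes = shuffled[len(module_proteins): cfg.n_proteins]
    pairs = list(zip(module_genes, module_proteins)) + list(
        zip(other_genes, other_proteins)
    )
    pairs.sort()

    snps, genes, signal_genes = make_association(cfg, module_genes, rng)
    candidates = make_candidates(module_genes, cfg, gene_ids, rng)
    return SyntheticDataset(
        config=cfg,
        network=network,
        module_proteins=module_proteins,
        snps=snps,
        genes=genes,
        gene_protein_map=pairs,
        module_genes=list(module_genes),
        signal_genes=signal_genes,
        candidates=candidates,
    )


def generate_pair(
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Two studies of the same disease: shared network, module, layout and
    candidates, but independent association noise — the setting for
    cross-dataset reproducibility analysis."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    ds1 = generate_dataset(cfg, rng)
    snps2, _, signal2 = make_association(
        cfg, ds1.module_genes, rng, genes=ds1.genes
    )
    ds2 = SyntheticDataset(
        config=cfg,
        network=ds1.network,
        module_proteins=ds1.module_proteins,
        snps=snps2,
        genes=ds1.genes,
        gene_protein_map=ds1.gene_protein_map,
        module_genes=ds1.module_genes,
        signal_genes=signal2,
        candidates=ds1.candidates,
    )
    return ds1, ds2


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the dataset in exactly the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "association": outdir / "association.tsv",
        "genes": outdir / "genes.tsv",
        "network": outdir / "ppi_edges.tsv",
        "map": outdir / "gene2protein.tsv",
        "candidates": outdir / "candidates.txt",
        "module_genes": outdir / "truth_module_genes.txt",
        "signal_genes": outdir / "truth_signal_genes.txt",
        "config": outdir / "sim_config.yaml",
    }
    write_tsv(
        [
            {"SNP": s.snp_id, "CHR": s.chrom, "BP": s.pos, "P": s.pvalue}
            for s in ds.snps
        ],
        paths["association"],
    )
    write_tsv(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end}
            for g in ds.genes
        ],
        paths["genes"],
    )
    with open(paths["network"], "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in ds.network.edges):
            fh.write(f"{u}\t{v}\n")
    write_tsv(
        [{"gene_id": g, "protein_id": p} for g, p in ds.gene_protein_map],
        paths["map"],
    )
    write_gene_list(ds.candidates, paths["candidates"])
    write_gene_list(ds.module_genes, paths["module_genes"])
    write_gene_list(ds.signal_genes, paths["signal_genes"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(ds.config.to_dict(), fh)
    return paths
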