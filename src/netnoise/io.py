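"""Readers and writers for the external file formats the pipeline touches.

Every reader validates its input into a domain type and returns a small
load report counting what was dropped, so runs are auditable.

Conventions
-----------
* Genomic coordinates are 1-based inclusive throughout.  BED input
  (0-based half-open) is converted at the boundary via ``dialect="bed"``.
* Chromosome names are normalized by stripping an optional ``chr`` prefix.
* The PPI network is an undirected simple graph: self-loops are removed
  and duplicate / reversed-duplicate edges collapsed, with counts logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SnpRecord",
    "GeneAnnotation",
    "LoadReport",
    "FormatError",
    "read_association_table",
    "read_gene_annotation",
    "read_edge_list",
    "read_gene_protein_map",
    "read_gene_list",
    "write_gene_list",
    "write_tsv",
    "normalize_chrom",
]


class FormatError(ValueError):
    """A file does not conform to the expected format."""


@dataclass(frozen=True)
class SnpRecord:
    """One per-SNP association result (family- or case/control-based)."""

    snp_id: str
    chrom: str
    pos: int  # 1-based basepairs
    pvalue: float  # in (0, 1]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: pos must be >= 1, got {self.pos}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(
                f"SNP {self.snp_id}: p-value must be in (0, 1], got {self.pvalue}"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene body on a chromosome, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass
class LoadReport:
    """Counts of records kept and dropped while loading a file."""

    path: str = ""
    n_read: int = 0
    n_kept: int = 0
    n_dropped_missing: int = 0
    n_dropped_invalid: int = 0
    n_duplicates: int = 0
    n_self_loops: int = 0
    messages: list[str] = field(default_factory=list)


def normalize_chrom(chrom: str) -> str:
    """Strip an optional 'chr' prefix; chromosome naming is otherwise kept."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


DEFAULT_ASSOC_COLUMNS: Mapping[str, str] = {
    "snp": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "p": "P",
}


def read_association_table(
    path: str | Path,
    column_config: Mapping[str, str] | None = None,
) -> tuple[list[SnpRecord], LoadReport]:
    """Read a PLINK-style whitespace/tab-delimited association table.

    Parameters
    ----------
    path:
        Path to the table.  Must have a header row.
    column_config:
        Maps the logical names ``snp``, ``chrom``, ``pos``, ``p`` to column
        headers in the file.  Defaults to PLINK's ``SNP/CHR/BP/P``.

    Returns
    -------
    (records, report):
        Validated records; rows with missing or non-numeric p-values, or
        p-values outside (0, 1], are dropped and counted in the report.

    Raises
    ------
    FormatError
        If a required column is absent or the file is empty.
    """
    path = Path(path)
    cols = dict(DEFAULT_ASSOC_COLUMNS)
    if column_config:
        cols.update(column_config)
    import csv

    try:
        # dtype=str + Python float(): pandas' numeric parsers are off by an
        # ulp on some values, which would break write/read round trips
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except (pd.errors.EmptyDataError, csv.Error):
        raise FormatError(f"{path}: association table is empty") from None
    if df.empty:
        raise FormatError(f"{path}: association table has a header but no rows")
    for logical, name in cols.items():
        if name not in df.columns:
            raise FormatError(
                f"{path}: required column {name!r} (for {logical!r}) not found; "
                f"available: {list(df.columns)}"
            )

    def _to_float(series: pd.Series) -> pd.Series:
        def conv(v):
            try:
                return float(v)
            except (TypeError, ValueError):
                return float("nan")

        return series.map(conv)

    report = LoadReport(path=str(path), n_read=len(df))
    pvals = _to_float(df[cols["p"]])
    pos = _to_float(df[cols["pos"]])
    missing = pvals.isna() | pos.isna()
    report.n_dropped_missing = int(missing.sum())
    invalid = (~missing) & ((pvals <= 0) | (pvals > 1) | (pos < 1))
    report.n_dropped_invalid = int(invalid.sum())
    keep = ~(missing | invalid)

    records = [
        SnpRecord(
            snp_id=str(s),
            chrom=normalize_chrom(c),
            pos=int(bp),
            pvalue=float(p),
        )
        for s, c, bp, p in zip(
            df.loc[keep, cols["snp"]],
            df.loc[keep, cols["chrom"]],
            pos[keep],
            pvals[keep],
        )
    ]
    seen: set[str] = set()
    unique: list[SnpRecord] = []
    for rec in records:
        if rec.snp_id in seen:
            report.n_duplicates += 1
            continue
        seen.add(rec.snp_id)
        unique.append(rec)
    report.n_kept = len(unique)
    if report.n_dropped_missing or report.n_dropped_invalid:
        logger.warning(
            "%s: dropped %d rows with missing and %d with invalid p/pos",
            path,
            report.n_dropped_missing,
            report.n_dropped_invalid,
        )
    return unique, report


def read_gene_annotation(
    path: str | Path,
    dialect: str = "tsv1",
) -> tuple[list[GeneAnnotation], LoadReport]:
    """Read gene bodies from a BED-like file.

    ``dialect="tsv1"`` expects 1-based inclusive columns
    gene_id/chrom/start/end with a header; ``dialect="bed"`` expects
    headerless BED (chrom, start0, end, name) and converts 0-based
    half-open to 1-based inclusive at this boundary.
    """
    path = Path(path)
    report = LoadReport(path=str(path))
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    if dialect == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene_id"], usecols=range(4),
        )
        starts = df["start"].astype(int) + 1  # 0-based half-open -> 1-based
        ends = df["end"].astype(int)
    elif dialect == "tsv1":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"gene_id", "chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"{path}: gene annotation needs columns {sorted(required)}"
            )
        starts = df["start"].astype(int)
        ends = df["end"].astype(int)
    else:
        raise ValueError(f"unknown gene annotation dialect {dialect!r}")
    report.n_read = len(df)
    for gid, chrom, s, e in zip(df["gene_id"], df["chrom"], starts, ends):
        gid = str(gid)
        if gid in seen:
            report.n_duplicates += 1
            continue
        seen.add(gid)
        genes.append(GeneAnnotation(gid, normalize_chrom(str(chrom)), int(s), int(e)))
    report.n_kept = len(genes)
    return genes, report


def read_edge_list(path: str | Path) -> tuple[nx.Graph, LoadReport]:
    """Read a two-column TSV of protein-protein interactions.

    Returns an undirected simple :class:`networkx.Graph`: self-loops are
    removed and duplicate edges (either orientation) collapsed, with
    counts in the report.  Malformed lines raise with their line number.
    """
    path = Path(path)
    report = LoadReport(path=str(path))
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise FormatError(
                    f"{path}:{lineno}: expected two protein ids, got {line!r}"
                )
            a, b = parts[0].strip(), parts[1].strip()
            report.n_read += 1
            if a == b:
                report.n_self_loops += 1
                graph.add_node(a)
                continue
            if graph.has_edge(a, b):
                report.n_duplicates += 1
                continue
            graph.add_edge(a, b)
    report.n_kept = graph.number_of_edges()
    if report.n_read == 0:
        logger.warning("%s: edge list is empty", path)
        report.messages.append("empty edge list")
    return graph, report


def read_gene_protein_map(path: str | Path) -> tuple[list[tuple[str, str]], LoadReport]:
    """Read a two-column TSV mapping gene ids to protein ids.

    Duplicate pairs are collapsed (counted); a gene may map to several
    proteins and vice versa.
    """
    path = Path(path)
    report = LoadReport(path=str(path))
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if line.lower().startswith("gene_id"):
                continue  # optional header
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise FormatError(
                    f"{path}:{lineno}: expected gene_id and protein_id, got {line!r}"
                )
            pair = (parts[0].strip(), parts[1].strip())
            report.n_read += 1
            if pair in seen:
                report.n_duplicates += 1
                continue
            seen.add(pair)
            pairs.append(pair)
    report.n_kept = len(pairs)
    return pairs, report


def read_gene_list(path: str | Path) -> tuple[set[str], LoadReport]:
    """Read a one-gene-per-line candidate list; '#' comments and blanks ignored."""
    path = Path(path)
    report = LoadReport(path=str(path))
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            report.n_read += 1
            if line in genes:
                report.n_duplicates += 1
            genes.add(line)
    report.n_kept = len(genes)
    return genes, report


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    """Write gene ids one per line, sorted for reproducible output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for g in sorted(set(map(str, genes))):
            fh.write(f"{g}\n")


def write_tsv(records: pd.DataFrame | Sequence[Mapping], path: str | Path) -> None:
    """Write records as a TSV with header (the pipeline's output format)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False)
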