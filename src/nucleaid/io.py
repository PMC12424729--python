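"""Readers and writers for every on-disk format the pipeline touches.

Dialect contracts (all plain text, tab-separated unless stated):

* BED3+/narrowPeak: tabs required; ``browser``/``track`` and ``#`` comment
  lines skipped; column 4 (when present) is the interval name, otherwise
  ``peak_<i>`` is generated; extra narrowPeak columns are ignored.  All
  coordinates are read and written 0-based half-open, and no operation
  elsewhere re-interprets the coordinate base.
* BEDPE: >= 6 columns; anchors normalized so anchor1 precedes anchor2 by
  (chrom, start); interchromosomal pairs retained and flagged.
* Methylation table: ``chrom  pos  level`` with an optional header
  (detected by a non-numeric ``pos``); positions are 0-based CpG cytosine
  coordinates, levels are fractions in [0, 1].
* Contact matrix: a whitespace-separated dense square grid plus a BED of
  uniform-width bins on one chromosome; the matrix is symmetrized by
  averaging with its transpose on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import DataError, ParseError
from .intervals import GenomicInterval, PeakSet
from .loops import ContactMatrix, Loop

__all__ = [
    "GeneModel",
    "read_bed",
    "write_bed",
    "write_narrowpeak",
    "read_bedpe",
    "write_bedpe",
    "read_methylation_table",
    "write_methylation_table",
    "read_bedgraph",
    "read_contact_matrix",
    "write_contact_matrix",
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_models",
    "write_gene_models",
]

PathLike = Union[str, Path]

_SKIP_PREFIXES = ("#", "browser", "track")


def _data_lines(path: PathLike):
    """Yield (1-based line number, stripped line) skipping comments/blank lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def _parse_int(value: str, what: str, path: PathLike, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(
            f"{path}: line {lineno}: non-integer {what} {value!r}"
        ) from None


# ---------------------------------------------------------------------------
# BED / narrowPeak


def read_bed(path: PathLike, label: str = "") -> PeakSet:
    """Read BED3+ (narrowPeak accepted; columns beyond 6 ignored).

    Intervals come back 0-based half-open and sorted; records lacking a
    name column get ``peak_<i>`` names.
    """
    intervals: List[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected >= 3 tab-separated columns")
        chrom = fields[0]
        start = _parse_int(fields[1], "start", path, lineno)
        end = _parse_int(fields[2], "end", path, lineno)
        if not chrom:
            raise ParseError(f"{path}: line {lineno}: empty chromosome name")
        if not (0 <= start < end):
            raise ParseError(
                f"{path}: line {lineno}: invalid interval [{start}, {end})"
            )
        name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else None
        score: Optional[float] = None
        if len(fields) > 4 and fields[4] not in ("", "."):
            try:
                score = float(fields[4])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric score {fields[4]!r}"
                ) from None
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-", ".") else None
        intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
    return PeakSet(intervals, label=label or Path(path).stem)


def _bed_fields(iv: GenomicInterval, n_cols: int) -> List[str]:
    fields = [iv.chrom, str(iv.start), str(iv.end)]
    if n_cols >= 4:
        fields.append(iv.name if iv.name is not None else ".")
    if n_cols >= 5:
        fields.append("." if iv.score is None else format(iv.score, "g"))
    if n_cols >= 6:
        fields.append(iv.strand if iv.strand is not None else ".")
    return fields


def write_bed(peaks: PeakSet, path: PathLike, header: Optional[str] = None) -> None:
    """Write BED; column count adapts to the richest interval in the set."""
    n_cols = 3
    for iv in peaks:
        if iv.strand is not None:
            n_cols = max(n_cols, 6)
        elif iv.score is not None:
            n_cols = max(n_cols, 5)
        elif iv.name is not None:
            n_cols = max(n_cols, 4)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for iv in peaks:
            fh.write("\t".join(_bed_fields(iv, n_cols)) + "\n")


def write_narrowpeak(
    peaks: PeakSet, path: PathLike, header: Optional[str] = None
) -> None:
    """Write ENCODE 10-column narrowPeak; summit column set to -1 (unused)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for iv in peaks:
            score = 0 if iv.score is None else iv.score
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name or ".",
                        format(score, "g"),
                        iv.strand or ".",
                        format(score, "g"),
                        "-1",
                        "-1",
                        "-1",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BEDPE


def read_bedpe(path: PathLike) -> List[Loop]:
    """Read loops; anchors normalized to genomic order; interchromosomal kept."""
    loops: List[Loop] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(f"{path}: line {lineno}: expected >= 6 tab-separated columns")
        c1 = fields[0]
        s1 = _parse_int(fields[1], "start1", path, lineno)
        e1 = _parse_int(fields[2], "end1", path, lineno)
        c2 = fields[3]
        s2 = _parse_int(fields[4], "start2", path, lineno)
        e2 = _parse_int(fields[5], "end2", path, lineno)
        if not (0 <= s1 < e1) or not (0 <= s2 < e2):
            raise ParseError(f"{path}: line {lineno}: invalid anchor interval")
        loops.append(
            Loop.from_anchors(GenomicInterval(c1, s1, e1), GenomicInterval(c2, s2, e2))
        )
    return loops


def write_bedpe(loops: Sequence[Loop], path: PathLike, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for lp in loops:
            a, b = lp.anchor1, lp.anchor2
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n"
            )


# ---------------------------------------------------------------------------
# Methylation table


def read_methylation_table(path: PathLike) -> pd.DataFrame:
    """Read a per-CpG methylation table into a sorted DataFrame.

    Columns: ``chrom`` (str), ``pos`` (0-based int), ``level`` (float in
    [0, 1]).  A header row is detected by a non-numeric ``pos`` field.
    """
    chroms: List[str] = []
    poss: List[int] = []
    levels: List[float] = []
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
        if first:
            first = False
            try:
                int(fields[1])
            except ValueError:
                continue  # header row
        pos = _parse_int(fields[1], "pos", path, lineno)
        try:
            level = float(fields[2])
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: non-numeric level {fields[2]!r}"
            ) from None
        if not (0.0 <= level <= 1.0):
            raise ParseError(
                f"{path}: line {lineno}: methylation level {level} outside [0, 1]"
            )
        chroms.append(fields[0])
        poss.append(pos)
        levels.append(level)
    df = pd.DataFrame({"chrom": chroms, "pos": poss, "level": levels})
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_methylation_table(
    df: pd.DataFrame, path: PathLike, header: Optional[str] = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df[["chrom", "pos", "level"]].to_csv(
            fh, sep="\t", index=False, float_format="%.3f"
        )


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: PathLike) -> pd.DataFrame:
    """Read a bedGraph into a DataFrame (chrom, start, end, value), sorted."""
    rows = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}: line {lineno}: expected 4 columns")
        start = _parse_int(fields[1], "start", path, lineno)
        end = _parse_int(fields[2], "end", path, lineno)
        if not (0 <= start < end):
            raise ParseError(f"{path}: line {lineno}: invalid interval")
        try:
            value = float(fields[3])
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: non-numeric value {fields[3]!r}"
            ) from None
        rows.append((fields[0], start, end, value))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Contact matrix (dense TSV dialect + bins BED)


def read_contact_matrix(path_matrix: PathLike, path_bins: PathLike) -> ContactMatrix:
    """Read a dense per-chromosome contact matrix.

    The bins BED must describe uniform-width, contiguous bins on a single
    chromosome; the grid is symmetrized by averaging ``(M + M.T) / 2``.
    """
    bins = read_bed(path_bins)
    chroms = bins.chromosomes()
    if len(chroms) != 1:
        raise DataError(f"bins file must cover one chromosome, got {chroms}")
    widths = bins.widths()
    if len(set(widths.tolist())) != 1:
        raise DataError("bins must have uniform width")
    resolution = int(widths[0])
    starts = np.array([iv.start for iv in bins], dtype=np.int64)
    values = np.loadtxt(path_matrix, dtype=float, ndmin=2)
    if values.shape != (len(bins), len(bins)):
        raise DataError(
            f"matrix dimension {values.shape} does not match {len(bins)} bins"
        )
    values = (values + values.T) / 2.0
    return ContactMatrix(
        chrom=chroms[0], resolution=resolution, bin_starts=starts, values=values
    )


def write_contact_matrix(
    matrix: ContactMatrix, path_matrix: PathLike, path_bins: PathLike
) -> None:
    np.savetxt(path_matrix, matrix.values, fmt="%.6g", delimiter="\t")
    bins = PeakSet(
        [
            GenomicInterval(
                matrix.chrom, int(s), int(s) + matrix.resolution, name=f"bin_{i}"
            )
            for i, s in enumerate(matrix.bin_starts)
        ]
    )
    write_bed(bins, path_bins)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read a FASTA into {chrom: upper-case sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Dict[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Counts matrix + sample sheet


def read_counts(path: PathLike) -> pd.DataFrame:
    """Features x samples integer count grid; first column = feature id."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate feature ids")
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative counts")
    return df.astype(np.int64)


def write_counts(df: pd.DataFrame, path: PathLike, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index_label="feature")


def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    """Sample sheet: columns sample, condition, replicate; indexed by sample."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "condition", "replicate"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: sample sheet needs columns {sorted(required)}")
    return df.set_index("sample")


def write_sample_sheet(df: pd.DataFrame, path: PathLike, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Gene models


@dataclass(frozen=True)
class GeneModel:
    """A gene: TSS plus gene body, with optional exon intervals.

    TSS convention: for + strand genes ``tss == body.start``; for - strand
    genes ``tss == body.end - 1`` (the last covered base).
    """

    gene_id: str
    chrom: str
    tss: int
    body: GenomicInterval
    strand: str
    exons: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id}: strand must be + or -")
        if not (self.body.start <= self.tss < self.body.end):
            raise DataError(f"gene {self.gene_id}: TSS outside gene body")


def read_gene_models(path: PathLike) -> List[GeneModel]:
    """Read a gene-model TSV.

    Columns: gene_id, chrom, strand, tss, body_start, body_end and an
    optional ``exons`` column of ``start-end`` pairs joined by ``;``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    genes: List[GeneModel] = []
    for row in df.itertuples(index=False):
        exons: Tuple[Tuple[int, int], ...] = ()
        raw = getattr(row, "exons", None)
        if isinstance(raw, str) and raw and raw != ".":
            exons = tuple(
                (int(a), int(b)) for a, b in (pair.split("-") for pair in raw.split(";"))
            )
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                tss=int(row.tss),
                body=GenomicInterval(
                    str(row.chrom), int(row.body_start), int(row.body_end)
                ),
                strand=str(row.strand),
                exons=exons,
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: PathLike, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("gene_id\tchrom\tstrand\ttss\tbody_start\tbody_end\texons\n")
        for g in genes:
            exons = ";".join(f"{a}-{b}" for a, b in g.exons) or "."
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t"
                f"{g.body.start}\t{g.body.end}\t{exons}\n"
            )
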