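"""Readers and writers for every on-disk format the pipeline touches.

One coordinate convention rules the package: 0-based, half-open
``[start, end)`` intervals, BED-native. UCSC rmsk-style tables already store
``genoStart`` 0-based, so no shift is applied on read or write. Strand is
parsed and preserved but ignored by every overlap computation downstream.

All tabular outputs are UTF-8, tab-delimited, with a header line.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "GenomicInterval",
    "BedRecord",
    "RepeatLocus",
    "AlignedRead",
    "GeneModel",
    "read_bed",
    "write_bed",
    "read_reads",
    "read_rmsk",
    "write_rmsk",
    "write_repeats_bed",
    "read_gene_table",
    "write_gene_table",
    "read_go_association",
    "write_go_association",
    "read_expression",
    "write_expression",
    "read_chrom_sizes",
    "write_chrom_sizes",
]

VALID_STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """A malformed record in an input file, with file/line context."""

    def __init__(self, message: str, path: str | Path | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f", line {line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")
        self.path = str(path) if path is not None else None
        self.line = line


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared base pairs; 0 when chromosomes differ."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, slots=True)
class BedRecord:
    interval: GenomicInterval
    name: str = "."
    score: float = 0.0


@dataclass(frozen=True, slots=True)
class RepeatLocus:
    """One RepeatMasker-annotated interval; the unit of counting."""

    interval: GenomicInterval
    locus_id: str
    rep_name: str
    rep_class: str = "."
    rep_family: str = "."


@dataclass(frozen=True, slots=True)
class AlignedRead:
    interval: GenomicInterval
    library: str = "."


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene as a transcription start..end span (no exon structure)."""

    gene_id: str
    symbol: str
    interval: GenomicInterval

    @property
    def strand(self) -> str:
        return self.interval.strand


# ---------------------------------------------------------------------------
# BED

def _parse_bed_line(fields: list[str], path, lineno: int, chrom_sizes) -> BedRecord:
    if len(fields) < 3:
        raise FormatError(f"BED line has {len(fields)} fields, need >= 3", path, lineno)
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise FormatError(f"non-integer coordinate in {fields[1]!r}/{fields[2]!r}", path, lineno)
    if start < 0 or start >= end:
        raise FormatError(f"invalid interval {chrom}:{start}-{end} (need 0 <= start < end)", path, lineno)
    if chrom_sizes is not None:
        if chrom not in chrom_sizes:
            raise FormatError(f"unknown chromosome {chrom!r}", path, lineno)
        if end > chrom_sizes[chrom]:
            raise FormatError(f"interval end {end} beyond {chrom} size {chrom_sizes[chrom]}", path, lineno)
    name = fields[3] if len(fields) > 3 else "."
    try:
        score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
    except ValueError:
        raise FormatError(f"non-numeric score {fields[4]!r}", path, lineno)
    strand = fields[5] if len(fields) > 5 else "."
    if strand not in VALID_STRANDS:
        raise FormatError(f"invalid strand {strand!r}", path, lineno)
    return BedRecord(GenomicInterval(chrom, start, end, strand), name, score)


def read_bed(path: str | Path, chrom_sizes: Mapping[str, int] | None = None) -> list[BedRecord]:
    """Read BED3/BED6 into 0-based half-open records.

    Invalid lines raise :class:`FormatError` carrying the line number. Track
    lines, comments and blank lines are skipped.
    """
    out: list[BedRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            out.append(_parse_bed_line(line.split("\t"), path, lineno, chrom_sizes))
    return out


def write_bed(records: Iterable[BedRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for r in records:
            iv = r.interval
            score = f"{r.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.name}\t{score}\t{iv.strand}\n")


def read_reads(path: str | Path, library: str | None = None) -> list[AlignedRead]:
    """Read a BED file of aligned single-end reads, one record per read."""
    lib = library if library is not None else Path(path).stem
    return [AlignedRead(r.interval, lib) for r in read_bed(path)]


# ---------------------------------------------------------------------------
# rmsk-style repeat annotation

RMSK_COLUMNS = ["genoName", "genoStart", "genoEnd", "strand", "repName", "repClass", "repFamily"]


def read_rmsk(path: str | Path, keep_classes: Sequence[str] | None = None) -> list[RepeatLocus]:
    """Read a UCSC rmsk-style TSV into :class:`RepeatLocus` records.

    ``genoStart`` is treated as 0-based (UCSC table convention). A
    ``locus_id`` column is honored when present and synthesized as
    ``repName:chrom:start-end`` otherwise. ``keep_classes`` optionally
    restricts to the given ``repClass`` values (all classes kept by default).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in RMSK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"rmsk table missing required column(s) {missing}", path)
    loci: list[RepeatLocus] = []
    seen: set[str] = set()
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            start, end = int(d["genoStart"]), int(d["genoEnd"])
        except ValueError:
            raise FormatError("non-integer rmsk coordinate", path, lineno)
        if keep_classes is not None and d["repClass"] not in keep_classes:
            continue
        strand = d["strand"] if d["strand"] in VALID_STRANDS else "."
        try:
            iv = GenomicInterval(d["genoName"], start, end, strand)
        except ValueError as exc:
            raise FormatError(str(exc), path, lineno)
        locus_id = d.get("locus_id") or f"{d['repName']}:{d['genoName']}:{start}-{end}"
        if locus_id in seen:
            raise FormatError(f"duplicate locus_id {locus_id!r}", path, lineno)
        seen.add(locus_id)
        loci.append(RepeatLocus(iv, locus_id, d["repName"], d["repClass"], d["repFamily"]))
    return loci


def write_rmsk(loci: Iterable[RepeatLocus], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(RMSK_COLUMNS + ["locus_id"]) + "\n")
        for loc in loci:
            iv = loc.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{loc.rep_name}\t{loc.rep_class}\t{loc.rep_family}\t{loc.locus_id}\n"
            )


def write_repeats_bed(loci: Iterable[RepeatLocus], path: str | Path) -> None:
    write_bed((BedRecord(l.interval, l.locus_id) for l in loci), path)


# ---------------------------------------------------------------------------
# gene models, GO association, expression

GENE_COLUMNS = ["gene_id", "symbol", "chrom", "strand", "txStart", "txEnd"]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a refFlat-like gene TSV (gene_id, symbol, chrom, strand, txStart, txEnd)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gene table missing required column(s) {missing}", path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        if d["gene_id"] in seen:
            raise FormatError(f"duplicate gene_id {d['gene_id']!r}", path, lineno)
        seen.add(d["gene_id"])
        try:
            start, end = int(d["txStart"]), int(d["txEnd"])
        except ValueError:
            raise FormatError("non-integer gene coordinate", path, lineno)
        try:
            iv = GenomicInterval(d["chrom"], start, end, d["strand"])
        except ValueError as exc:
            raise FormatError(str(exc), path, lineno)
        genes.append(GeneModel(d["gene_id"], d["symbol"], iv))
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in genes:
            iv = g.interval
            fh.write(f"{g.gene_id}\t{g.symbol}\t{iv.chrom}\t{iv.strand}\t{iv.start}\t{iv.end}\n")


def read_go_association(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a gene->GO-term association TSV.

    Returns ``(gene -> set of term ids, term id -> term name)``; repeated
    (gene, term) pairs are de-duplicated. A third ``term_name`` column is
    optional.
    """
    assoc: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return assoc, names
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise FormatError("association row needs gene_id and term_id", path, lineno)
            gene, term = row[0], row[1]
            assoc.setdefault(gene, set()).add(term)
            if len(row) > 2 and row[2]:
                names[term] = row[2]
    return assoc, names


def write_go_association(
    assoc: Mapping[str, set[str]], path: str | Path, term_names: Mapping[str, str] | None = None
) -> None:
    names = term_names or {}
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("gene_id\tterm_id\tterm_name\n")
        for gene in sorted(assoc):
            for term in sorted(assoc[gene]):
                fh.write(f"{gene}\t{term}\t{names.get(term, '')}\n")


EXPRESSION_COLUMNS = ["gene_id", "symbol", "expr_NS", "expr_NSch", "expr_HS", "expr_HSch"]


def read_expression(path: str | Path):
    """Read a four-group expression TSV into :class:`~repeathet.rescue.ExpressionRecord` rows."""
    from .rescue import ExpressionRecord

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"expression table missing required column(s) {missing}", path)
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            vals = [float(d[c]) for c in EXPRESSION_COLUMNS[2:]]
        except ValueError:
            raise FormatError("non-numeric expression value", path, lineno)
        if any(v < 0 for v in vals):
            raise FormatError("negative expression value", path, lineno)
        records.append(ExpressionRecord(d["gene_id"], d["symbol"], *vals))
    return records


def write_expression(records, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(EXPRESSION_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.symbol}\t{r.expr_ns:.4f}\t{r.expr_nsch:.4f}\t"
                f"{r.expr_hs:.4f}\t{r.expr_hsch:.4f}\n"
            )


# ---------------------------------------------------------------------------
# chromosome sizes

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError("chrom sizes row needs name and length", path, lineno)
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError:
                raise FormatError(f"non-integer chromosome length {fields[1]!r}", path, lineno)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("chrom\tlength\n")
        for chrom in sizes:
            fh.write(f"{chrom}\t{sizes[chrom]}\n")
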