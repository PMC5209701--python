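"""Read-to-repeat counting under the 90%-of-minimum overlap criterion.

A read and a repeat locus are "overlapped" when the shared base pairs,
divided by the length of the *shorter* of the two intervals, reach a minimum
fraction (0.90 by default, inclusive). A 50 bp read fully inside a 300 bp
repeat therefore counts (50/50 = 1.0), and so does a 300 bp repeat fully
covered by a longer read. By default a read increments every locus that
satisfies the rule — nested or adjacent repeats can legitimately share a
read — with an optional unique-best assignment for sensitivity analysis.

Per-locus counts are normalized to RPM (reads per million mapped), with the
total mapped reads of the library as the denominator, not only the
repeat-hitting reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genomeio import AlignedRead, GenomicInterval, RepeatLocus

__all__ = [
    "OverlapRule",
    "LibraryCounts",
    "overlap_fraction",
    "count_reads",
    "normalize_rpm",
    "write_counts",
    "read_counts",
]


@dataclass(frozen=True, slots=True)
class OverlapRule:
    """Minimum shared fraction of the shorter interval, in (0, 1]."""

    min_fraction: float = 0.90

    def __post_init__(self) -> None:
        if not (0.0 < self.min_fraction <= 1.0):
            raise ValueError(f"min_fraction must be in (0, 1], got {self.min_fraction}")


@dataclass
class LibraryCounts:
    """Per-locus read counts and RPM for one sequencing library."""

    library: str
    library_size: int
    counts: dict[str, int] = field(default_factory=dict)
    rpm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError(f"library_size must be positive, got {self.library_size}")


def overlap_fraction(read: GenomicInterval, locus: GenomicInterval) -> float:
    """Shared bp divided by the length of the shorter interval, in [0, 1]."""
    shared = read.overlap_bp(locus)
    if shared == 0:
        return 0.0
    return shared / min(read.length, locus.length)


def _build_index(loci: Sequence[RepeatLocus]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, locus in enumerate(loci):
        iv = locus.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    return trees


def count_reads(
    reads: Iterable[AlignedRead],
    loci: Sequence[RepeatLocus],
    rule: OverlapRule = OverlapRule(),
    library: str | None = None,
    library_size: int | None = None,
    unique_best: bool = False,
) -> LibraryCounts:
    """Count reads per repeat locus under ``rule``.

    Every locus appears in the result (zero counts included). With
    ``unique_best`` a read goes only to the locus with the highest overlap
    fraction, ties broken by leftmost start then locus id; otherwise it goes
    to every qualifying locus. ``library_size`` defaults to the number of
    reads supplied; results are independent of read and locus order.
    """
    reads = list(reads)
    if library_size is None:
        library_size = len(reads)
    if library_size <= 0:
        raise ValueError("library_size must be positive (empty library cannot be normalized)")
    lib = library if library is not None else (reads[0].library if reads else ".")

    counts = {locus.locus_id: 0 for locus in loci}
    if len(counts) != len(loci):
        raise ValueError("locus_id values must be unique within the annotation")
    trees = _build_index(loci)
    for read in reads:
        iv = read.interval
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = []
        for node in tree.overlap(iv.start, iv.end):
            locus = loci[node.data]
            frac = overlap_fraction(iv, locus.interval)
            if frac >= rule.min_fraction:
                hits.append((frac, locus))
        if not hits:
            continue
        if unique_best:
            best = min(hits, key=lambda h: (-h[0], h[1].interval.start, h[1].locus_id))
            counts[best[1].locus_id] += 1
        else:
            for _, locus in hits:
                counts[locus.locus_id] += 1

    result = LibraryCounts(lib, library_size, counts)
    return normalize_rpm(result)


def normalize_rpm(counts: LibraryCounts, library_size: int | None = None) -> LibraryCounts:
    """Fill ``rpm = count * 1e6 / library_size`` for every locus."""
    if library_size is not None:
        if library_size <= 0:
            raise ValueError(f"library_size must be positive, got {library_size}")
        counts.library_size = library_size
    scale = 1e6 / counts.library_size
    counts.rpm = {locus_id: c * scale for locus_id, c in counts.counts.items()}
    return counts


def write_counts(counts: LibraryCounts, loci: Sequence[RepeatLocus], path: str | Path) -> None:
    """Write a counts TSV: locus_id, coords, rep_name, count, rpm."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# library={counts.library}\tlibrary_size={counts.library_size}\n")
        fh.write("locus_id\tchrom\tstart\tend\trep_name\tcount\trpm\n")
        for locus in loci:
            iv = locus.interval
            c = counts.counts[locus.locus_id]
            fh.write(
                f"{locus.locus_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{locus.rep_name}\t{c}\t{counts.rpm[locus.locus_id]:.6f}\n"
            )


def read_counts(path: str | Path) -> LibraryCounts:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    meta = dict(part.split("=", 1) for part in header.lstrip("# ").split("\t"))
    df = pd.read_csv(path, sep="\t", comment="#")
    lc = LibraryCounts(
        meta.get("library", Path(path).stem),
        int(meta["library_size"]),
        dict(zip(df["locus_id"], df["count"].astype(int))),
    )
    return normalize_rpm(lc)
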