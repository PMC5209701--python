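"""Locus-to-gene assignment over flanked gene territories.

A gene's *territory* is its transcription span extended by a fixed flank
(10 kb by default) on both sides, clipped to chromosome bounds. A repeat
locus is assigned to every gene whose territory it overlaps by at least one
base pair — proximity assignment deliberately does not reuse the 90%
read-counting rule. The module also computes the fraction of a territory
set covered by repetitive sequence, with all double-counting removed by
merging both interval sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .genomeio import GeneModel, GenomicInterval, RepeatLocus

__all__ = [
    "GeneTerritory",
    "make_territories",
    "assign_loci_to_genes",
    "merge_intervals",
    "repetitive_fraction",
]

DEFAULT_FLANK = 10_000


@dataclass(frozen=True, slots=True)
class GeneTerritory:
    gene_id: str
    territory: GenomicInterval
    flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError(f"flank must be >= 0, got {self.flank}")


def make_territories(
    genes: Iterable[GeneModel],
    flank: int = DEFAULT_FLANK,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GeneTerritory]:
    """Extend each gene by ``flank`` bp on both sides, clipping at bounds."""
    territories = []
    for gene in genes:
        iv = gene.interval
        start = max(0, iv.start - flank)
        end = iv.end + flank
        if chrom_sizes is not None and iv.chrom in chrom_sizes:
            end = min(end, chrom_sizes[iv.chrom])
        territories.append(GeneTerritory(gene.gene_id, GenomicInterval(iv.chrom, start, end, iv.strand), flank))
    return territories


def assign_loci_to_genes(
    loci: Sequence[RepeatLocus],
    genes: Sequence[GeneModel],
    flank: int = DEFAULT_FLANK,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[dict[str, list[str]], list[str]]:
    """Map each locus to the genes whose territory it touches (>= 1 bp).

    Returns ``(locus_id -> sorted gene ids, study gene list)`` where the
    study list is the de-duplicated, sorted union over all assigned loci.
    Loci hitting no territory map to an empty list.
    """
    territories = make_territories(genes, flank, chrom_sizes)
    trees: dict[str, IntervalTree] = {}
    for terr in territories:
        iv = terr.territory
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, terr.gene_id)

    assignment: dict[str, list[str]] = {}
    study: set[str] = set()
    for locus in loci:
        iv = locus.interval
        tree = trees.get(iv.chrom)
        hits = sorted({node.data for node in tree.overlap(iv.start, iv.end)}) if tree else []
        assignment[locus.locus_id] = hits
        study.update(hits)
    return assignment, sorted(study)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    """Merge overlapping/adjacent intervals per chromosome (strand ignored)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out = [list(spans[0])]
        for start, end in spans[1:]:
            if start <= out[-1][1]:
                out[-1][1] = max(out[-1][1], end)
            else:
                out.append([start, end])
        merged[chrom] = [(s, e) for s, e in out]
    return merged


def _intersection_bp(a: dict[str, list[tuple[int, int]]], b: dict[str, list[tuple[int, int]]]) -> int:
    total = 0
    for chrom, spans_a in a.items():
        spans_b = b.get(chrom)
        if not spans_b:
            continue
        i = j = 0
        while i < len(spans_a) and j < len(spans_b):
            lo = max(spans_a[i][0], spans_b[j][0])
            hi = min(spans_a[i][1], spans_b[j][1])
            if hi > lo:
                total += hi - lo
            if spans_a[i][1] < spans_b[j][1]:
                i += 1
            else:
                j += 1
    return total


def repetitive_fraction(
    territories: Sequence[GeneTerritory],
    repeats: Sequence[RepeatLocus],
) -> float:
    """Percent of the merged territory set covered by repetitive sequence.

    Both the territory set and the repeat set are merged to unions first, so
    overlapping territories and fragmented repeat annotations are not
    double-counted. Returns ``100 * |union(repeats) ∩ union(territories)| /
    |union(territories)|``.
    """
    if not territories:
        raise ValueError("repetitive_fraction needs at least one territory")
    terr_union = merge_intervals(t.territory for t in territories)
    terr_bp = sum(e - s for spans in terr_union.values() for s, e in spans)
    if not repeats:
        return 0.0
    rep_union = merge_intervals(r.interval for r in repeats)
    return 100.0 * _intersection_bp(rep_union, terr_union) / terr_bp
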