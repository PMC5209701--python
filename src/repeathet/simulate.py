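"""Synthetic four-library ChIP experiment over a repeat-annotated toy genome.

The generator emulates the study design end to end: an input-DNA library
and three H3K9me3 ChIP libraries (control, failing heart, failing heart
under chaetocin) sequenced over a small genome carrying a RepeatMasker-style
repeat annotation and simple single-span gene models. A chosen subset of
repeat loci is *planted* in four condition patterns:

================  =========  =========  ==========
class             ctrl       hf         treat
================  =========  =========  ==========
hfup_reversed     baseline   fold x     baseline
hfup_static       baseline   fold x     fold x
hfdown_reversed   fold x     baseline   fold x
hfdown_static     fold x     baseline   baseline
================  =========  =========  ==========

Every locus receives a baseline expected read count (``background_mean``)
in every library; planted loci have their ChIP expectation multiplied by
``planted_fold`` (>= 100, so they are callable under the 100-fold input
rule) in the conditions marked above. Expected counts are scaled by library
size so that the *RPM* fold versus input equals the intended fold exactly.
Reads assigned to a locus start uniformly inside it and fit entirely, so
the 90%-of-minimum overlap rule always fires for them; the remaining reads
of each library are scattered uniformly over the repeat-free genome, which
keeps ``background_mean`` the *whole* per-locus expectation (uniform
scatter across repeats would add a depth- and length-dependent extra term
on top of it). In ``exact`` noise mode every per-locus count equals its
(rounded) expectation; in ``poisson`` mode counts are Poisson-sampled
around the same means. A truth manifest records the planted direction,
reversal flag and territory-assigned genes of every locus.

The companion expression generator plants rescue genes that satisfy the
three-screen criteria with margin while every other gene violates at least
one criterion.

All randomness flows from one seeded NumPy generator: the same seed yields
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import genomeio
from .genomeio import (
    AlignedRead,
    BedRecord,
    GeneModel,
    GenomicInterval,
    RepeatLocus,
)
from .differential import Direction, LIBRARY_ROLES
from .rescue import ExpressionRecord

__all__ = [
    "SimConfig",
    "TruthRecord",
    "TruthManifest",
    "SimulatedDataset",
    "generate_dataset",
    "generate_expression",
]

PLANTED_CLASSES = ("hfup_reversed", "hfup_static", "hfdown_reversed", "hfdown_static")

#: Which conditions carry the elevated ChIP expectation, per planted class.
_ELEVATED = {
    "hfup_reversed": ("hf",),
    "hfup_static": ("hf", "treat"),
    "hfdown_reversed": ("ctrl", "treat"),
    "hfdown_static": ("ctrl",),
}

_TRUTH = {
    "hfup_reversed": (Direction.HF_UP, True),
    "hfup_static": (Direction.HF_UP, False),
    "hfdown_reversed": (Direction.HF_DOWN, True),
    "hfdown_static": (Direction.HF_DOWN, False),
}

_REPEAT_CATALOG = [
    ("B1_Rn", "SINE", "Alu"),
    ("L1_Rat1", "LINE", "L1"),
    ("RAL_ERV", "LTR", "ERVK"),
    ("RatSat1", "Satellite", "centr"),
    ("MER5A", "DNA", "hAT-Charlie"),
]

MITO_TERM_ID = "GO:0005739"
MITO_TERM_NAME = "mitochondrion"


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment; defaults give a small genome
    that runs in seconds yet exercises every pipeline stage."""

    seed: int = 17
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_repeats: int = 300
    repeat_length_range: tuple[int, int] = (300, 800)
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (5_000, 20_000)
    flank: int = 10_000
    read_length: int = 50
    library_sizes: dict[str, int] = field(
        default_factory=lambda: {role: 100_000 for role in LIBRARY_ROLES}
    )
    background_mean: float = 5.0
    planted: dict[str, int] = field(
        default_factory=lambda: {cls: 5 for cls in PLANTED_CLASSES}
    )
    planted_fold: float = 150.0
    noise_mode: str = "exact"
    mito_fraction: float = 0.3
    allow_nested: bool = False

    def validate(self) -> None:
        errors = []
        if self.seed < 0:
            errors.append("seed must be >= 0")
        if self.n_chroms < 1 or self.chrom_length < 1:
            errors.append("need at least one chromosome of positive length")
        if self.n_repeats < 0 or self.n_genes < 0:
            errors.append("feature counts must be >= 0")
        for name, (lo, hi) in (
            ("repeat_length_range", self.repeat_length_range),
            ("gene_length_range", self.gene_length_range),
        ):
            if not (0 < lo <= hi):
                errors.append(f"{name} must satisfy 0 < low <= high")
        if self.read_length < 1:
            errors.append("read_length must be >= 1")
        if self.repeat_length_range[0] < self.read_length:
            errors.append("repeats must be at least one read long so planted reads fit inside")
        if set(self.library_sizes) != set(LIBRARY_ROLES):
            errors.append(f"library_sizes must have exactly the keys {LIBRARY_ROLES}")
        elif any(s <= 0 for s in self.library_sizes.values()):
            errors.append("library sizes must be positive")
        if set(self.planted) - set(PLANTED_CLASSES):
            errors.append(f"planted classes must be among {PLANTED_CLASSES}")
        if any(v < 0 for v in self.planted.values()):
            errors.append("planted counts must be >= 0")
        if sum(self.planted.values()) > self.n_repeats:
            errors.append("planted totals exceed n_repeats")
        if self.background_mean < 0:
            errors.append("background_mean must be >= 0")
        if self.planted_fold < 100:
            errors.append("planted_fold must be >= 100 so planted loci clear the enrichment gate")
        if self.noise_mode not in ("exact", "poisson"):
            errors.append("noise_mode must be 'exact' or 'poisson'")
        if not (0.0 <= self.mito_fraction <= 1.0):
            errors.append("mito_fraction must be in [0, 1]")
        if self.flank < 0:
            errors.append("flank must be >= 0")
        if errors:
            raise ValueError("invalid SimConfig: " + "; ".join(errors))


@dataclass(frozen=True, slots=True)
class TruthRecord:
    locus_id: str
    true_direction: Direction
    true_reversed: bool
    assigned_gene_ids: tuple[str, ...]


@dataclass
class TruthManifest:
    records: dict[str, TruthRecord]

    def planted(self) -> list[TruthRecord]:
        return [r for r in self.records.values() if r.true_direction is not Direction.NONE]

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write("locus_id\ttrue_direction\ttrue_reversed\tassigned_gene_ids\n")
            for r in self.records.values():
                genes = ",".join(r.assigned_gene_ids)
                fh.write(f"{r.locus_id}\t{r.true_direction}\t{int(r.true_reversed)}\t{genes}\n")

    @classmethod
    def read(cls, path: str | Path) -> "TruthManifest":
        records: dict[str, TruthRecord] = {}
        with open(path, encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                locus_id, direction, rev, genes = line.rstrip("\n").split("\t")
                records[locus_id] = TruthRecord(
                    locus_id,
                    Direction(direction),
                    rev == "1",
                    tuple(g for g in genes.split(",") if g),
                )
        return cls(records)


@dataclass
class SimulatedDataset:
    config: SimConfig
    chrom_sizes: dict[str, int]
    repeats: list[RepeatLocus]
    genes: list[GeneModel]
    association: dict[str, set[str]]
    term_names: dict[str, str]
    reads: dict[str, list[AlignedRead]]
    expression: list[ExpressionRecord]
    rescue_gene_ids: list[str]
    manifest: TruthManifest

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every component in the pipeline's on-disk formats."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "chrom_sizes": out / "chrom_sizes.tsv",
            "repeats_rmsk": out / "repeats.rmsk.tsv",
            "repeats_bed": out / "repeats.bed",
            "genes": out / "genes.tsv",
            "association": out / "go_association.tsv",
            "expression": out / "expression.tsv",
            "manifest": out / "truth_manifest.tsv",
        }
        genomeio.write_chrom_sizes(self.chrom_sizes, paths["chrom_sizes"])
        genomeio.write_rmsk(self.repeats, paths["repeats_rmsk"])
        genomeio.write_repeats_bed(self.repeats, paths["repeats_bed"])
        genomeio.write_gene_table(self.genes, paths["genes"])
        genomeio.write_go_association(self.association, paths["association"], self.term_names)
        genomeio.write_expression(self.expression, paths["expression"])
        self.manifest.write(paths["manifest"])
        for role in LIBRARY_ROLES:
            p = out / f"reads_{role}.bed"
            paths[f"reads_{role}"] = p
            genomeio.write_bed(
                (
                    BedRecord(read.interval, f"{role}_{i}")
                    for i, read in enumerate(self.reads[role])
                ),
                p,
            )
        return paths


# ---------------------------------------------------------------------------
# feature placement

def _place_features(
    rng: np.random.Generator,
    chrom_sizes: Mapping[str, int],
    lengths: Sequence[int],
) -> list[GenomicInterval]:
    """Place features of the given lengths without mutual overlap.

    Features are distributed round-robin over chromosomes; within a
    chromosome the free space is split into random gaps around the features
    (classic stars-and-bars placement), which guarantees non-overlap.
    """
    chroms = list(chrom_sizes)
    per_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    order = rng.permutation(len(lengths))
    for pos, idx in enumerate(order):
        per_chrom[chroms[pos % len(chroms)]].append(int(lengths[idx]))
    intervals: list[GenomicInterval] = []
    for chrom in chroms:
        feats = per_chrom[chrom]
        if not feats:
            continue
        feats = [feats[i] for i in rng.permutation(len(feats))]
        free = chrom_sizes[chrom] - sum(feats)
        if free < 0:
            raise ValueError(
                f"chromosome {chrom} ({chrom_sizes[chrom]} bp) too short for "
                f"{len(feats)} features totalling {sum(feats)} bp"
            )
        cuts = np.sort(rng.integers(0, free + 1, size=len(feats)))
        offset = 0
        for i, length in enumerate(feats):
            start = int(cuts[i]) + offset
            intervals.append(GenomicInterval(chrom, start, start + length))
            offset += length
    intervals.sort(key=lambda iv: (iv.chrom, iv.start))
    return intervals


def _assign_genes_brute_force(
    repeats: Sequence[RepeatLocus], genes: Sequence[GeneModel], flank: int
) -> dict[str, tuple[str, ...]]:
    """Territory assignment by direct all-pairs scan (independent of the
    annotation module, so the manifest is genuine ground truth)."""
    out: dict[str, tuple[str, ...]] = {}
    for locus in repeats:
        iv = locus.interval
        hit = []
        for gene in genes:
            g = gene.interval
            if g.chrom == iv.chrom and iv.start < g.end + flank and iv.end > max(0, g.start - flank):
                hit.append(gene.gene_id)
        out[locus.locus_id] = tuple(sorted(hit))
    return out


# ---------------------------------------------------------------------------
# read generation

def _reads_in_locus(
    rng: np.random.Generator, locus: GenomicInterval, count: int, read_length: int
) -> list[GenomicInterval]:
    if count == 0:
        return []
    hi = locus.end - read_length
    starts = rng.integers(locus.start, hi + 1, size=count)
    return [GenomicInterval(locus.chrom, int(s), int(s) + read_length) for s in np.sort(starts)]


def _scatter_gaps(
    chrom_sizes: Mapping[str, int], repeats: Sequence[RepeatLocus], read_length: int
) -> list[tuple[str, int, int]]:
    """Start-position ranges (chrom, lo, hi inclusive) for reads that touch
    no repeat at all."""
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for r in repeats:
        by_chrom[r.interval.chrom].append((r.interval.start, r.interval.end))
    ranges: list[tuple[str, int, int]] = []
    for chrom, size in chrom_sizes.items():
        spans = sorted(by_chrom[chrom])
        cursor = 0
        for start, end in spans + [(size, size)]:
            lo, hi = cursor, start - read_length
            if hi >= lo:
                ranges.append((chrom, lo, hi))
            cursor = max(cursor, end)
    return ranges


def _scatter_reads(
    rng: np.random.Generator,
    chrom_sizes: Mapping[str, int],
    count: int,
    read_length: int,
    avoid: Sequence[RepeatLocus] | None,
) -> list[GenomicInterval]:
    if count == 0:
        return []
    if avoid is not None:
        ranges = _scatter_gaps(chrom_sizes, avoid, read_length)
        if not ranges:
            raise ValueError("no repeat-free gap can hold a read; genome too crowded")
        weights = np.array([hi - lo + 1 for _, lo, hi in ranges], dtype=float)
        picks = rng.choice(len(ranges), size=count, p=weights / weights.sum())
        out = []
        for idx in picks:
            chrom, lo, hi = ranges[idx]
            s = int(rng.integers(lo, hi + 1))
            out.append(GenomicInterval(chrom, s, s + read_length))
    else:
        chroms = list(chrom_sizes)
        weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
        picks = rng.choice(len(chroms), size=count, p=weights / weights.sum())
        out = []
        for idx in picks:
            chrom = chroms[idx]
            s = int(rng.integers(0, chrom_sizes[chrom] - read_length + 1))
            out.append(GenomicInterval(chrom, s, s + read_length))
    out.sort(key=lambda iv: (iv.chrom, iv.start))
    return out


# ---------------------------------------------------------------------------
# top-level generators

def generate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate the full dataset bundle for one seeded configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}

    # --- features -----------------------------------------------------------
    rep_lengths = rng.integers(
        config.repeat_length_range[0], config.repeat_length_range[1] + 1, size=config.n_repeats
    )
    gene_lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=config.n_genes
    )
    if config.allow_nested:
        rep_ivs = _place_features(rng, chrom_sizes, rep_lengths)
        gene_ivs = _place_features(rng, chrom_sizes, gene_lengths)
    else:
        joint = _place_features(rng, chrom_sizes, list(rep_lengths) + list(gene_lengths))
        # the shorter intervals are repeats (ranges are disjoint by default;
        # fall back to a length cut at the repeat maximum)
        cut = config.repeat_length_range[1]
        rep_ivs = [iv for iv in joint if iv.length <= cut][: config.n_repeats]
        gene_ivs = [iv for iv in joint if iv.length > cut]
        if len(rep_ivs) != config.n_repeats or len(gene_ivs) != config.n_genes:
            raise ValueError(
                "repeat_length_range and gene_length_range overlap; "
                "set allow_nested=True to place them independently"
            )

    repeats = []
    for i, iv in enumerate(rep_ivs):
        name, rep_class, rep_family = _REPEAT_CATALOG[int(rng.integers(len(_REPEAT_CATALOG)))]
        strand = "+" if rng.random() < 0.5 else "-"
        repeats.append(
            RepeatLocus(
                GenomicInterval(iv.chrom, iv.start, iv.end, strand),
                f"rep{i:05d}", name, rep_class, rep_family,
            )
        )
    genes = []
    for i, iv in enumerate(gene_ivs):
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(f"g{i:04d}", f"Gene{i}", GenomicInterval(iv.chrom, iv.start, iv.end, strand))
        )

    # --- plant condition patterns ------------------------------------------
    n_planted = sum(config.planted.get(cls, 0) for cls in PLANTED_CLASSES)
    chosen = rng.choice(config.n_repeats, size=n_planted, replace=False) if n_planted else np.array([], int)
    class_of: dict[str, str] = {}
    cursor = 0
    for cls in PLANTED_CLASSES:
        for idx in chosen[cursor : cursor + config.planted.get(cls, 0)]:
            class_of[repeats[int(idx)].locus_id] = cls
        cursor += config.planted.get(cls, 0)

    # --- truth manifest -----------------------------------------------------
    gene_assignment = _assign_genes_brute_force(repeats, genes, config.flank)
    records = {}
    for locus in repeats:
        cls = class_of.get(locus.locus_id)
        direction, rev = _TRUTH[cls] if cls else (Direction.NONE, False)
        records[locus.locus_id] = TruthRecord(
            locus.locus_id, direction, rev, gene_assignment[locus.locus_id]
        )
    manifest = TruthManifest(records)

    # --- GO association -----------------------------------------------------
    association, term_names = _make_association(rng, genes, manifest, config.mito_fraction)

    # --- reads --------------------------------------------------------------
    exact = config.noise_mode == "exact"
    input_size = config.library_sizes["input"]
    reads: dict[str, list[AlignedRead]] = {}
    for role in LIBRARY_ROLES:
        lib_size = config.library_sizes[role]
        depth_scale = lib_size / input_size
        lib_reads: list[GenomicInterval] = []
        total_locus_reads = 0
        for locus in repeats:
            cls = class_of.get(locus.locus_id)
            mult = (
                config.planted_fold
                if cls is not None and role in _ELEVATED[cls]
                else 1.0
            )
            if role == "input":
                mult = 1.0
            mean = config.background_mean * mult * depth_scale
            count = int(round(mean)) if exact else int(rng.poisson(mean))
            total_locus_reads += count
            lib_reads.extend(_reads_in_locus(rng, locus.interval, count, config.read_length))
        n_scatter = lib_size - total_locus_reads
        if n_scatter < 0:
            raise ValueError(
                f"library {role!r}: per-locus reads ({total_locus_reads}) exceed "
                f"library size {lib_size}; increase the library size or lower background_mean"
            )
        lib_reads.extend(
            _scatter_reads(rng, chrom_sizes, n_scatter, config.read_length, repeats)
        )
        lib_reads.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        reads[role] = [AlignedRead(iv, role) for iv in lib_reads]

    # --- expression ---------------------------------------------------------
    expression, rescue_ids = generate_expression(
        config,
        n_rescue=min(10, config.n_genes),
        n_total_genes=config.n_genes,
        gene_ids=[g.gene_id for g in genes],
        symbols={g.gene_id: g.symbol for g in genes},
        rng=rng,
    )

    return SimulatedDataset(
        config, chrom_sizes, repeats, genes, association, term_names,
        reads, expression, rescue_ids, manifest,
    )


def _make_association(
    rng: np.random.Generator,
    genes: Sequence[GeneModel],
    manifest: TruthManifest,
    mito_fraction: float,
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Annotate genes with a focal 'mitochondrion' term plus filler terms.

    Genes hosting reversed HF-up planted loci are preferentially given the
    focal term, so the downstream GO stage has signal to find; random genes
    top the focal set up to ``mito_fraction`` of all genes.
    """
    gene_ids = [g.gene_id for g in genes]
    focal = {
        gid
        for rec in manifest.records.values()
        if rec.true_direction is Direction.HF_UP and rec.true_reversed
        for gid in rec.assigned_gene_ids
    }
    target = max(len(focal), int(round(mito_fraction * len(gene_ids))))
    pool = [g for g in gene_ids if g not in focal]
    extra = rng.choice(len(pool), size=min(target - len(focal), len(pool)), replace=False)
    focal |= {pool[int(i)] for i in extra}

    filler_terms = [
        ("GO:0005737", "cytoplasm", 0.5),
        ("GO:0005634", "nucleus", 0.35),
        ("GO:0005886", "plasma membrane", 0.25),
    ]
    association: dict[str, set[str]] = {}
    term_names = {MITO_TERM_ID: MITO_TERM_NAME}
    for gid in gene_ids:
        terms = set()
        if gid in focal:
            terms.add(MITO_TERM_ID)
        for term_id, name, p in filler_terms:
            term_names[term_id] = name
            if rng.random() < p:
                terms.add(term_id)
        if not terms:
            terms.add(filler_terms[0][0])
        association[gid] = terms
    return association, term_names


def generate_expression(
    config: SimConfig,
    n_rescue: int,
    n_total_genes: int,
    gene_ids: Sequence[str] | None = None,
    symbols: Mapping[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ExpressionRecord], list[str]]:
    """Four-group expression table with ``n_rescue`` planted rescue genes.

    Planted genes satisfy all three screen criteria with margin
    (HS/NS in [0.15, 0.45], HS+ch/HS in [1.6, 2.4], HS >= 150); every other
    gene violates exactly one criterion, cycling through the three, so the
    screen's decision boundaries are all exercised. Deterministic under the
    config seed when no generator is passed in.
    """
    if n_rescue > n_total_genes:
        raise ValueError(f"n_rescue ({n_rescue}) exceeds n_total_genes ({n_total_genes})")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(n_total_genes)]
    if len(gene_ids) != n_total_genes:
        raise ValueError("gene_ids length must equal n_total_genes")
    symbols = symbols or {}

    rescue_idx = set(
        int(i) for i in rng.choice(n_total_genes, size=n_rescue, replace=False)
    )
    records: list[ExpressionRecord] = []
    rescue_ids: list[str] = []
    violation_cycle = 0
    for i, gid in enumerate(gene_ids):
        symbol = symbols.get(gid, gid.capitalize())
        if i in rescue_idx:
            hs = float(rng.uniform(150, 600))
            ratio_hf = float(rng.uniform(0.15, 0.45))
            ratio_treat = float(rng.uniform(1.6, 2.4))
            rescue_ids.append(gid)
        else:
            mode = violation_cycle % 3
            violation_cycle += 1
            hs = float(rng.uniform(150, 600))
            ratio_hf = float(rng.uniform(0.15, 0.45))
            ratio_treat = float(rng.uniform(1.6, 2.4))
            if mode == 0:      # not down-regulated enough
                ratio_hf = float(rng.uniform(0.7, 1.6))
            elif mode == 1:    # not restored by treatment
                ratio_treat = float(rng.uniform(0.7, 1.25))
            else:              # too lowly expressed in HF
                hs = float(rng.uniform(10, 80))
        ns = hs / ratio_hf
        records.append(
            ExpressionRecord(
                gid,
                symbol,
                expr_ns=round(ns, 4),
                expr_nsch=round(ns * float(rng.uniform(0.9, 1.1)), 4),
                expr_hs=round(hs, 4),
                expr_hsch=round(hs * ratio_treat, 4),
            )
        )
    return records, rescue_ids


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["repeat_length_range"] = list(config.repeat_length_range)
    d["gene_length_range"] = list(config.gene_length_range)
    return d


def config_from_dict(data: Mapping) -> SimConfig:
    d = dict(data)
    for key in ("repeat_length_range", "gene_length_range"):
        if key in d:
            d[key] = tuple(d[key])
    unknown = set(d) - set(SimConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown simulation option(s): {sorted(unknown)}")
    return SimConfig(**d)
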