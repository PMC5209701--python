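import numpy as np
import pytest

from repeathet.genomeio import AlignedRead, GenomicInterval, RepeatLocus
from repeathet.simulate import SimConfig, generate_dataset


def make_interval(chrom, start, end, strand="."):
    return GenomicInterval(chrom, start, end, strand)


def make_locus(chrom, start, end, locus_id, name="REP"):
    return RepeatLocus(GenomicInterval(chrom, start, end), locus_id, name)


def make_read(chrom, start, end, library="lib"):
    return AlignedRead(GenomicInterval(chrom, start, end), library)


def random_instance(rng, n_reads, n_loci, n_chroms=3, span=100_000):
    """A random reads/loci instance for oracle-equivalence checks."""
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    loci = []
    for i in range(n_loci):
        chrom = chroms[int(rng.integers(n_chroms))]
        start = int(rng.integers(0, span - 1000))
        length = int(rng.integers(50, 1000))
        loci.append(make_locus(chrom, start, start + length, f"L{i:04d}"))
    reads = []
    for _ in range(n_reads):
        chrom = chroms[int(rng.integers(n_chroms))]
        start = int(rng.integers(0, span - 200))
        length = int(rng.integers(20, 200))
        reads.append(make_read(chrom, start, start + length))
    return reads, loci


def brute_force_counts(reads, loci, min_fraction):
    """O(n*m) all-pairs counting oracle, no interval index."""
    counts = {locus.locus_id: 0 for locus in loci}
    for read in reads:
        for locus in loci:
            shared = read.interval.overlap_bp(locus.interval)
            if shared == 0:
                continue
            frac = shared / min(read.interval.length, locus.interval.length)
            if frac >= min_fraction:
                counts[locus.locus_id] += 1
    return counts


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)


@pytest.fixture(scope="session")
def small_exact_dataset():
    """One small noise-free dataset shared across tests (generation ~1 s)."""
    config = SimConfig(
        seed=17,
        n_chroms=2,
        chrom_length=400_000,
        n_repeats=120,
        n_genes=20,
        library_sizes={role: 20_000 for role in ("input", "ctrl", "hf", "treat")},
        planted={"hfup_reversed": 3, "hfup_static": 3, "hfdown_reversed": 3, "hfdown_static": 3},
        noise_mode="exact",
    )
    return generate_dataset(config)
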