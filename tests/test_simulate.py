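"""The synthetic four-library experiment and its ground-truth manifest."""

import filecmp

import numpy as np
import pytest

from repeathet.counting import OverlapRule, count_reads, overlap_fraction
from repeathet.differential import Direction, LIBRARY_ROLES
from repeathet.simulate import (
    PLANTED_CLASSES,
    SimConfig,
    TruthManifest,
    generate_dataset,
)


def tiny_config(**overrides):
    base = dict(
        seed=17,
        n_chroms=2,
        chrom_length=200_000,
        n_repeats=40,
        n_genes=8,
        library_sizes={role: 5_000 for role in LIBRARY_ROLES},
        planted={cls: 1 for cls in PLANTED_CLASSES},
        noise_mode="exact",
    )
    base.update(overrides)
    return SimConfig(**base)


class TestConfigValidation:
    def test_planted_totals_must_fit(self):
        with pytest.raises(ValueError, match="planted totals"):
            generate_dataset(tiny_config(n_repeats=3))

    def test_planted_fold_must_clear_the_enrichment_gate(self):
        with pytest.raises(ValueError, match="planted_fold"):
            generate_dataset(tiny_config(planted_fold=50))

    def test_overfull_chromosome_is_an_error(self):
        with pytest.raises(ValueError, match="too short"):
            generate_dataset(tiny_config(chrom_length=2_000, n_repeats=40))

    def test_library_roles_are_fixed(self):
        with pytest.raises(ValueError, match="library_sizes"):
            generate_dataset(tiny_config(library_sizes={"input": 1000}))


class TestManifest:
    def test_one_planted_locus_per_class(self):
        ds = generate_dataset(tiny_config())
        planted = ds.manifest.planted()
        assert len(planted) == 4
        seen = {(rec.true_direction, rec.true_reversed) for rec in planted}
        assert seen == {
            (Direction.HF_UP, True), (Direction.HF_UP, False),
            (Direction.HF_DOWN, True), (Direction.HF_DOWN, False),
        }

    def test_manifest_covers_every_locus_once(self):
        ds = generate_dataset(tiny_config())
        assert set(ds.manifest.records) == {l.locus_id for l in ds.repeats}

    def test_manifest_round_trips(self, tmp_path):
        ds = generate_dataset(tiny_config())
        p = tmp_path / "truth.tsv"
        ds.manifest.write(p)
        assert TruthManifest.read(p).records == ds.manifest.records


class TestDeterminism:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            generate_dataset(tiny_config(seed=17)).write(tmp_path / sub)
        names = [p.name for p in sorted((tmp_path / "a").iterdir())]
        match, mismatch, errors = filecmp.cmpfiles(tmp_path / "a", tmp_path / "b", names, shallow=False)
        assert sorted(match) == sorted(names) and not mismatch and not errors

    def test_different_seeds_differ(self):
        a = generate_dataset(tiny_config(seed=1))
        b = generate_dataset(tiny_config(seed=2))
        assert [l.interval for l in a.repeats] != [l.interval for l in b.repeats]


class TestGeometry:
    def test_features_do_not_overlap_by_default(self):
        ds = generate_dataset(tiny_config(n_repeats=60, n_genes=10))
        features = sorted(
            [l.interval for l in ds.repeats] + [g.interval for g in ds.genes],
            key=lambda iv: (iv.chrom, iv.start),
        )
        for a, b in zip(features, features[1:]):
            assert a.chrom != b.chrom or a.end <= b.start

    def test_features_fit_inside_chromosomes(self):
        ds = generate_dataset(tiny_config())
        for iv in [l.interval for l in ds.repeats] + [g.interval for g in ds.genes]:
            assert 0 <= iv.start < iv.end <= ds.chrom_sizes[iv.chrom]

    def test_planted_reads_lie_fully_inside_their_locus(self):
        ds = generate_dataset(tiny_config())
        planted_ids = {rec.locus_id for rec in ds.manifest.planted()}
        loci = {l.locus_id: l for l in ds.repeats}
        for rec_id in planted_ids:
            locus = loci[rec_id]
            covering = [
                r for r in ds.reads["hf"]
                if overlap_fraction(r.interval, locus.interval) > 0
                and r.interval.start >= locus.interval.start
                and r.interval.end <= locus.interval.end
            ]
            # elevated or baseline, the locus-assigned reads sit fully inside
            assert all(
                overlap_fraction(r.interval, locus.interval) == 1.0 for r in covering
            )


class TestExactModeCounts:
    def test_library_sizes_are_exact(self):
        ds = generate_dataset(tiny_config())
        for role in LIBRARY_ROLES:
            assert len(ds.reads[role]) == ds.config.library_sizes[role]

    def test_per_locus_counts_equal_expectations(self):
        cfg = tiny_config(background_mean=4.0, planted_fold=120.0)
        ds = generate_dataset(cfg)
        counts = {
            role: count_reads(ds.reads[role], ds.repeats, library_size=len(ds.reads[role]))
            for role in LIBRARY_ROLES
        }
        elevated = {
            "hfup_reversed": ("hf",),
            "hfup_static": ("hf", "treat"),
            "hfdown_reversed": ("ctrl", "treat"),
            "hfdown_static": ("ctrl",),
        }
        truth_class = {}
        for rec in ds.manifest.planted():
            truth_class[rec.locus_id] = (
                f"{'hfup' if rec.true_direction is Direction.HF_UP else 'hfdown'}"
                f"_{'reversed' if rec.true_reversed else 'static'}"
            )
        for locus in ds.repeats:
            cls = truth_class.get(locus.locus_id)
            for role in LIBRARY_ROLES:
                mult = cfg.planted_fold if cls and role in elevated[cls] else 1.0
                if role == "input":
                    mult = 1.0
                assert counts[role].counts[locus.locus_id] == round(cfg.background_mean * mult)

    def test_planted_hfup_fold_recomputed_at_or_above_100(self):
        ds = generate_dataset(tiny_config(planted_fold=150.0, background_mean=5.0))
        counts = {
            role: count_reads(ds.reads[role], ds.repeats, library_size=len(ds.reads[role]))
            for role in LIBRARY_ROLES
        }
        for rec in ds.manifest.planted():
            if rec.true_direction is Direction.HF_UP:
                fold = counts["hf"].rpm[rec.locus_id] / counts["input"].rpm[rec.locus_id]
                assert fold >= 100.0


class TestPoissonMode:
    def test_counts_fluctuate_around_the_exact_means(self):
        exact = generate_dataset(tiny_config(seed=23, noise_mode="exact"))
        noisy = generate_dataset(tiny_config(seed=23, noise_mode="poisson"))
        c_exact = count_reads(exact.reads["input"], exact.repeats, library_size=len(exact.reads["input"]))
        c_noisy = count_reads(noisy.reads["input"], noisy.repeats, library_size=len(noisy.reads["input"]))
        a = np.array(list(c_exact.counts.values()), dtype=float)
        b = np.array(list(c_noisy.counts.values()), dtype=float)
        assert not np.array_equal(a, b)
        # same expectation: means agree loosely, variance appears
        assert b.mean() == pytest.approx(a.mean(), rel=0.35)
        assert b.var() > 0

    def test_poisson_mode_is_deterministic_per_seed(self, tmp_path):
        for sub in ("a", "b"):
            generate_dataset(tiny_config(seed=5, noise_mode="poisson")).write(tmp_path / sub)
        names = [p.name for p in sorted((tmp_path / "a").iterdir())]
        match, mismatch, errors = filecmp.cmpfiles(tmp_path / "a", tmp_path / "b", names, shallow=False)
        assert not mismatch and not errors
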