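"""Enrichment-vs-input calls, HF-up/HF-down classification and reversal."""

import pytest

from repeathet.counting import LibraryCounts, normalize_rpm
from repeathet.differential import (
    DifferentialCall,
    Direction,
    EnrichmentCall,
    call_enrichment,
    classify_differential,
    summarize,
)

LIB = 10**6  # 1 read == 1 RPM, so counts below read directly as RPM


def make_counts(per_locus: dict[str, dict[str, int]]) -> dict[str, LibraryCounts]:
    """per_locus: locus_id -> {input: n, ctrl: n, hf: n, treat: n} at 1e6 depth."""
    out = {}
    for role in ("input", "ctrl", "hf", "treat"):
        counts = {locus: vals[role] for locus, vals in per_locus.items()}
        out[role] = normalize_rpm(LibraryCounts(role, LIB, counts))
    return out


def call_one(input=5, ctrl=5, hf=5, treat=5, **kwargs) -> EnrichmentCall:
    counts = make_counts({"L": {"input": input, "ctrl": ctrl, "hf": hf, "treat": treat}})
    (call,) = call_enrichment(counts, **kwargs)
    return call


class TestCallEnrichment:
    def test_threshold_is_inclusive_at_100_fold(self):
        call = call_one(input=5, hf=500)
        assert call.fold_hf == pytest.approx(100.0)
        assert call.enriched_hf

    def test_equal_rpm_is_not_enriched(self):
        call = call_one(input=5, hf=5)
        assert call.fold_hf == pytest.approx(1.0)
        assert not call.enriched_hf

    def test_zero_input_uses_rpm_floor(self):
        call = call_one(input=0, hf=150, rpm_floor=1.0)
        assert call.fold_hf == pytest.approx(150.0)
        assert call.enriched_hf

    def test_default_floor_is_one_reads_worth(self):
        # input library of 1e6 reads -> floor 1 RPM; 99 RPM stays below 100x
        call = call_one(input=0, hf=99)
        assert not call.enriched_hf
        call = call_one(input=0, hf=100)
        assert call.enriched_hf

    def test_min_input_reads_gates_enrichment(self):
        call = call_one(input=0, hf=500, min_input_reads=1)
        assert not call.enriched_hf

    def test_mismatched_universe_rejected(self):
        counts = make_counts({"L": {"input": 1, "ctrl": 1, "hf": 1, "treat": 1}})
        counts["hf"] = normalize_rpm(LibraryCounts("hf", LIB, {"other": 1}))
        with pytest.raises(ValueError):
            call_enrichment(counts)

    def test_nonpositive_threshold_rejected(self):
        counts = make_counts({"L": {"input": 1, "ctrl": 1, "hf": 1, "treat": 1}})
        with pytest.raises(ValueError):
            call_enrichment(counts, fold_threshold=0)


class TestClassifyDifferential:
    def classify_one(self, **kwargs):
        extra = {k: kwargs.pop(k) for k in ("min_cond_fold", "reversal_margin") if k in kwargs}
        (diff,) = classify_differential([call_one(**kwargs)], **extra)
        return diff

    def test_hf_up_reversed(self):
        diff = self.classify_one(input=1, ctrl=1, hf=200, treat=3)
        assert diff.direction is Direction.HF_UP and diff.reversed

    def test_candidate_gate_blocks_unenriched_loci(self):
        # clear RPM ordering but nothing reaches 100x input -> no call
        diff = self.classify_one(input=5, ctrl=5, hf=50, treat=5)
        assert diff.direction is Direction.NONE and not diff.reversed

    def test_hf_down_without_restoration(self):
        diff = self.classify_one(input=1, ctrl=300, hf=2, treat=2)
        assert diff.direction is Direction.HF_DOWN and not diff.reversed

    def test_hf_down_reversed(self):
        diff = self.classify_one(input=1, ctrl=300, hf=2, treat=250)
        assert diff.direction is Direction.HF_DOWN and diff.reversed

    def test_tie_between_conditions_is_no_call(self):
        diff = self.classify_one(input=1, ctrl=200, hf=200, treat=0)
        assert diff.direction is Direction.NONE

    def test_min_cond_fold_requires_margin(self):
        diff = self.classify_one(input=1, ctrl=150, hf=200, treat=0, min_cond_fold=2.0)
        assert diff.direction is Direction.NONE
        diff = self.classify_one(input=1, ctrl=90, hf=200, treat=0, min_cond_fold=2.0)
        assert diff.direction is Direction.HF_UP

    def test_reversal_margin_requires_movement(self):
        diff = self.classify_one(input=1, ctrl=1, hf=200, treat=195, reversal_margin=10.0)
        assert diff.direction is Direction.HF_UP and not diff.reversed

    def test_swapping_ctrl_and_hf_mirrors_directions(self, rng):
        per_locus = {
            f"L{i}": {
                "input": int(rng.integers(0, 10)),
                "ctrl": int(rng.integers(0, 2000)),
                "hf": int(rng.integers(0, 2000)),
                "treat": int(rng.integers(0, 2000)),
            }
            for i in range(200)
        }
        fwd = classify_differential(call_enrichment(make_counts(per_locus)))
        swapped = {k: dict(v, ctrl=v["hf"], hf=v["ctrl"]) for k, v in per_locus.items()}
        rev = classify_differential(call_enrichment(make_counts(swapped)))
        mirror = {Direction.HF_UP: Direction.HF_DOWN, Direction.HF_DOWN: Direction.HF_UP,
                  Direction.NONE: Direction.NONE}
        for a, b in zip(fwd, rev):
            assert b.direction is mirror[a.direction]

    def test_raising_threshold_shrinks_candidate_set(self, rng):
        per_locus = {
            f"L{i}": {
                "input": int(rng.integers(0, 10)),
                "ctrl": int(rng.integers(0, 2000)),
                "hf": int(rng.integers(0, 2000)),
                "treat": int(rng.integers(0, 2000)),
            }
            for i in range(200)
        }
        counts = make_counts(per_locus)

        def called(threshold):
            diffs = classify_differential(call_enrichment(counts, fold_threshold=threshold))
            return {d.locus_id for d in diffs if d.direction is not Direction.NONE}

        loose, strict = called(50), called(200)
        assert strict <= loose

    def test_reversed_requires_a_direction(self):
        with pytest.raises(ValueError):
            DifferentialCall("L", Direction.NONE, True)


class TestSummarize:
    def _diffs(self, n_up, n_up_rev, n_down, n_down_rev):
        out = []
        for i in range(n_up):
            out.append(DifferentialCall(f"u{i}", Direction.HF_UP, i < n_up_rev))
        for i in range(n_down):
            out.append(DifferentialCall(f"d{i}", Direction.HF_DOWN, i < n_down_rev))
        return out

    def test_percentage_to_one_decimal(self):
        summary = summarize(self._diffs(0, 0, 335, 35))
        assert summary.pct_hf_down_reversed == 10.4

    def test_rounding_up_to_one_decimal(self):
        summary = summarize(self._diffs(6550, 6534, 0, 0))
        assert summary.pct_hf_up_reversed == 99.8

    def test_empty_denominator_convention(self):
        summary = summarize(self._diffs(0, 0, 3, 1))
        assert summary.pct_hf_up_reversed == 0.0
        assert summary.n_hf_up == 0
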