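"""Input-normalized enrichment calls and three-condition differential logic.

The study design pools one H3K9me3 ChIP library per condition — control
heart, failing heart (HF), and failing heart under the H3K9
methyltransferase inhibitor chaetocin — plus one input-DNA library. A
repeat locus is *enriched* in a condition when its ChIP RPM is at least a
fold threshold (default 100, inclusive) above the input RPM. Loci enriched
in control or in HF are candidates; among candidates, higher RPM in HF than
control is "HF-up", lower is "HF-down", a tie is no call. A locus is
*reversed* when the treated library moves strictly back toward the control
level (down for HF-up loci, up for HF-down loci).

Zero input coverage would give infinite folds, so the input RPM is floored
at one read's worth (1e6 / input library size) by default; both the floor
and a hard minimum-input-reads filter are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .counting import LibraryCounts
from .genomeio import RepeatLocus

__all__ = [
    "Direction",
    "EnrichmentCall",
    "DifferentialCall",
    "DiffSummary",
    "LIBRARY_ROLES",
    "call_enrichment",
    "classify_differential",
    "summarize",
    "write_diff",
    "read_diff",
    "write_summary",
]

#: Canonical role names for the four libraries, in pipeline order.
LIBRARY_ROLES = ("input", "ctrl", "hf", "treat")


class Direction(str, Enum):
    HF_UP = "HF_UP"
    HF_DOWN = "HF_DOWN"
    NONE = "NONE"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


@dataclass(frozen=True, slots=True)
class EnrichmentCall:
    locus_id: str
    rpm_input: float
    rpm_ctrl: float
    rpm_hf: float
    rpm_treat: float
    fold_ctrl: float
    fold_hf: float
    fold_treat: float
    enriched_ctrl: bool
    enriched_hf: bool
    enriched_treat: bool


@dataclass(frozen=True, slots=True)
class DifferentialCall:
    locus_id: str
    direction: Direction
    reversed: bool

    def __post_init__(self) -> None:
        if self.reversed and self.direction is Direction.NONE:
            raise ValueError("a locus with no direction cannot be reversed")


@dataclass(frozen=True, slots=True)
class DiffSummary:
    n_hf_up: int
    n_hf_down: int
    n_hf_up_reversed: int
    n_hf_down_reversed: int
    pct_hf_up_reversed: float
    pct_hf_down_reversed: float


def call_enrichment(
    counts: Mapping[str, LibraryCounts],
    fold_threshold: float = 100.0,
    rpm_floor: float | None = None,
    min_input_reads: int = 0,
) -> list[EnrichmentCall]:
    """Compute ChIP/input folds and enrichment flags per locus.

    ``counts`` maps the roles ``input``, ``ctrl``, ``hf``, ``treat`` to
    :class:`LibraryCounts` over the same locus universe. The fold for
    condition X is ``rpm_X / max(rpm_input, rpm_floor)``; ``rpm_floor``
    defaults to one read's worth of the input library. Loci with fewer than
    ``min_input_reads`` input reads are never flagged enriched.
    """
    missing = [role for role in LIBRARY_ROLES if role not in counts]
    if missing:
        raise ValueError(f"missing library role(s): {missing}")
    if fold_threshold <= 0:
        raise ValueError(f"fold_threshold must be positive, got {fold_threshold}")
    universe = list(counts["input"].counts)
    for role in LIBRARY_ROLES[1:]:
        if set(counts[role].counts) != set(universe):
            raise ValueError(f"library {role!r} covers a different locus universe than input")
    if rpm_floor is None:
        rpm_floor = 1e6 / counts["input"].library_size
    if rpm_floor <= 0:
        raise ValueError(f"rpm_floor must be positive, got {rpm_floor}")

    calls: list[EnrichmentCall] = []
    for locus_id in universe:
        rpm_in = counts["input"].rpm[locus_id]
        denom = max(rpm_in, rpm_floor)
        measurable = counts["input"].counts[locus_id] >= min_input_reads
        rpm = {role: counts[role].rpm[locus_id] for role in LIBRARY_ROLES[1:]}
        fold = {role: rpm[role] / denom for role in rpm}
        enriched = {role: measurable and fold[role] >= fold_threshold for role in fold}
        calls.append(
            EnrichmentCall(
                locus_id,
                rpm_in,
                rpm["ctrl"],
                rpm["hf"],
                rpm["treat"],
                fold["ctrl"],
                fold["hf"],
                fold["treat"],
                enriched["ctrl"],
                enriched["hf"],
                enriched["treat"],
            )
        )
    return calls


def classify_differential(
    calls: Iterable[EnrichmentCall],
    min_cond_fold: float = 1.0,
    reversal_margin: float = 0.0,
) -> list[DifferentialCall]:
    """Assign HF_UP / HF_DOWN / NONE and a reversal flag per locus.

    Candidates are loci enriched in control or in HF. With the default
    ``min_cond_fold`` of 1.0 any strict RPM difference between HF and
    control sets the direction; larger values require
    ``rpm_hf > min_cond_fold * rpm_ctrl`` (and symmetrically) for a call.
    Reversal requires the treated RPM to move strictly back toward control
    by more than ``reversal_margin`` (RPM units).
    """
    if min_cond_fold < 1.0:
        raise ValueError(f"min_cond_fold must be >= 1, got {min_cond_fold}")
    if reversal_margin < 0.0:
        raise ValueError(f"reversal_margin must be >= 0, got {reversal_margin}")
    out: list[DifferentialCall] = []
    for call in calls:
        direction = Direction.NONE
        rev = False
        if call.enriched_ctrl or call.enriched_hf:
            if call.rpm_hf > min_cond_fold * call.rpm_ctrl:
                direction = Direction.HF_UP
                rev = call.rpm_treat < call.rpm_hf - reversal_margin
            elif call.rpm_ctrl > min_cond_fold * call.rpm_hf:
                direction = Direction.HF_DOWN
                rev = call.rpm_treat > call.rpm_hf + reversal_margin
        out.append(DifferentialCall(call.locus_id, direction, rev))
    return out


def summarize(diffs: Iterable[DifferentialCall]) -> DiffSummary:
    """Count directions and reversals; percentages reported to 1 decimal."""
    n_up = n_down = rev_up = rev_down = 0
    for d in diffs:
        if d.direction is Direction.HF_UP:
            n_up += 1
            rev_up += d.reversed
        elif d.direction is Direction.HF_DOWN:
            n_down += 1
            rev_down += d.reversed
    pct_up = round(100.0 * rev_up / n_up, 1) if n_up else 0.0
    pct_down = round(100.0 * rev_down / n_down, 1) if n_down else 0.0
    return DiffSummary(n_up, n_down, rev_up, rev_down, pct_up, pct_down)


# ---------------------------------------------------------------------------
# TSV round-trip for the pipeline

DIFF_COLUMNS = [
    "locus_id", "chrom", "start", "end",
    "rpm_input", "rpm_ctrl", "rpm_hf", "rpm_treat",
    "fold_ctrl", "fold_hf", "fold_treat",
    "direction", "reversed",
]


def write_diff(
    calls: Sequence[EnrichmentCall],
    diffs: Sequence[DifferentialCall],
    loci: Sequence[RepeatLocus],
    path: str | Path,
) -> None:
    by_id = {l.locus_id: l for l in loci}
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(DIFF_COLUMNS) + "\n")
        for call, diff in zip(calls, diffs, strict=True):
            if call.locus_id != diff.locus_id:
                raise ValueError("enrichment and differential calls out of sync")
            iv = by_id[call.locus_id].interval
            fh.write(
                f"{call.locus_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{call.rpm_input:.6f}\t{call.rpm_ctrl:.6f}\t{call.rpm_hf:.6f}\t{call.rpm_treat:.6f}\t"
                f"{call.fold_ctrl:.6f}\t{call.fold_hf:.6f}\t{call.fold_treat:.6f}\t"
                f"{diff.direction}\t{int(diff.reversed)}\n"
            )


def read_diff(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["direction"] = df["direction"].map(Direction)
    df["reversed"] = df["reversed"].astype(bool)
    return df


def write_summary(summary: DiffSummary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(
            "n_hf_up\tn_hf_down\tn_hf_up_reversed\tn_hf_down_reversed\t"
            "pct_hf_up_reversed\tpct_hf_down_reversed\n"
        )
        fh.write(
            f"{summary.n_hf_up}\t{summary.n_hf_down}\t{summary.n_hf_up_reversed}\t"
            f"{summary.n_hf_down_reversed}\t{summary.pct_hf_up_reversed:.1f}\t"
            f"{summary.pct_hf_down_reversed:.1f}\n"
        )
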