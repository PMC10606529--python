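"""Locus-level artifact filters.

Repeat-derived alignments are prone to mapping artifacts, so loci are
screened on three rules, applied in order:

1. **read support** — a locus with fewer than two mapped reads is
   discarded (single-read evidence is indistinguishable from noise);
2. **start consistency** — if any read starts more than 100 bp from the
   locus's most common read start, the locus is discarded (genuine L1
   transcription initiates at the promoter, so read starts cluster);
3. **5' proximity** — if the most common start lies more than 1.5 kb from
   the reference L1 start position, the locus is discarded (starts deep
   inside the element suggest read-through or truncation artifacts
   rather than autonomous transcription).

A locus that fails any rule contributes no reads downstream; its verdict
records the first rule violated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .intervals import L1Region

REASON_OK = "ok"
REASON_TOO_FEW = "too_few_reads"
REASON_INCONSISTENT = "inconsistent_starts"
REASON_TOO_FAR = "start_too_far"


@dataclass
class LocusReadSet:
    """The containment-passing primary reads assigned to one locus."""

    region: L1Region
    read_starts: list[int]
    read_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.read_starts) != len(self.read_ids):
            raise ValueError("read_starts and read_ids must be parallel")


@dataclass
class LocusVerdict:
    region: L1Region
    n_reads: int
    modal_start: Optional[int]
    kept: bool
    reason: str

    def __post_init__(self) -> None:
        if self.kept != (self.reason == REASON_OK):
            raise ValueError("kept flag inconsistent with reason")


def modal_start(starts: Sequence[int]) -> int:
    """Most frequent start; frequency ties break to the smallest coordinate."""
    if not starts:
        raise ValueError("modal_start of empty list")
    counts = Counter(starts)
    best_count = max(counts.values())
    return min(s for s, c in counts.items() if c == best_count)


def reference_start_point(region: L1Region, strand_aware: bool = False) -> int:
    """The locus 'start position' the 5'-proximity rule measures against.

    By default the lower genomic coordinate (BED start) regardless of
    strand, matching coordinate-based interval commands; with
    ``strand_aware`` the biological 5' end is used instead (BED end for
    minus-strand loci).
    """
    if strand_aware and region.interval.strand == "-":
        return region.end
    return region.start


def evaluate_locus(
    locus_set: LocusReadSet,
    min_reads: int = 2,
    start_window: int = 100,
    max_start_offset: int = 1500,
    strand_aware_start: bool = False,
    trim_outlier_reads: bool = False,
) -> LocusVerdict:
    """Apply the three artifact rules to one locus, in order.

    Thresholds are inclusive on the keep side: a deviation of exactly
    ``start_window`` bp, or a modal start exactly ``max_start_offset`` bp
    from the reference start, still passes. With ``trim_outlier_reads``
    the start-consistency rule drops outlier reads instead of the whole
    locus (off by default).
    """
    starts = list(locus_set.read_starts)
    n = len(starts)
    if n < min_reads:
        return LocusVerdict(locus_set.region, n, modal_start(starts) if starts else None,
                            kept=False, reason=REASON_TOO_FEW)
    mode = modal_start(starts)
    deviants = [s for s in starts if abs(s - mode) > start_window]
    if deviants:
        if not trim_outlier_reads:
            return LocusVerdict(locus_set.region, n, mode, kept=False,
                                reason=REASON_INCONSISTENT)
        keep_mask = [abs(s - mode) <= start_window for s in starts]
        starts = [s for s, k in zip(starts, keep_mask) if k]
        locus_set = LocusReadSet(
            region=locus_set.region,
            read_starts=starts,
            read_ids=[r for r, k in zip(locus_set.read_ids, keep_mask) if k],
        )
        n = len(starts)
        if n < min_reads:
            return LocusVerdict(locus_set.region, n, mode, kept=False,
                                reason=REASON_TOO_FEW)
        mode = modal_start(starts)
    ref_start = reference_start_point(locus_set.region, strand_aware_start)
    if abs(mode - ref_start) > max_start_offset:
        return LocusVerdict(locus_set.region, n, mode, kept=False, reason=REASON_TOO_FAR)
    return LocusVerdict(locus_set.region, n, mode, kept=True, reason=REASON_OK)


def apply_locus_filters(
    locus_sets: Sequence[LocusReadSet],
    min_reads: int = 2,
    start_window: int = 100,
    max_start_offset: int = 1500,
    strand_aware_start: bool = False,
    trim_outlier_reads: bool = False,
) -> list[LocusVerdict]:
    """Per-locus verdicts; each locus is judged independently."""
    return [
        evaluate_locus(
            ls,
            min_reads=min_reads,
            start_window=start_window,
            max_start_offset=max_start_offset,
            strand_aware_start=strand_aware_start,
            trim_outlier_reads=trim_outlier_reads,
        )
        for ls in locus_sets
    ]


def surviving_read_ids(
    locus_sets: Sequence[LocusReadSet], verdicts: Sequence[LocusVerdict]
) -> set[str]:
    """Reads at kept loci (union across loci)."""
    kept_uids = {v.region.uid for v in verdicts if v.kept}
    out: set[str] = set()
    for ls in locus_sets:
        if ls.region.uid in kept_uids:
            out.update(ls.read_ids)
    return out


def write_verdicts_tsv(verdicts: Sequence[LocusVerdict], path) -> None:
    with open(path, "w") as fh:
        fh.write("uid\tcategory\tn_reads\tmodal_start\tkept\treason\n")
        for v in verdicts:
            modal = "" if v.modal_start is None else v.modal_start
            fh.write(
                f"{v.region.uid}\t{v.region.category}\t{v.n_reads}\t{modal}\t"
                f"{int(v.kept)}\t{v.reason}\n"
            )
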