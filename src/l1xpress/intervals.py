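"""Genomic interval primitives shared across the pipeline.

All coordinates are 0-based half-open ([start, end)), the BED convention.
SAM/GTF inputs are converted at parse time so no other module ever sees
1-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

CATEGORIES = ("active", "inactive", "orf2")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval on a named sequence.

    ``strand`` is '+', '-' or '.' (unknown); ``name`` is a free-text label
    (BED column 4).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share at least one base (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class L1Region:
    """A categorized L1 reference locus (L1Base2 model).

    category is one of ``active`` (full-length, both ORFs intact),
    ``inactive`` (full-length, non-intact) or ``orf2`` (intact only in
    ORF2). ``uid`` is the L1Base2 unique identifier; ``subfamily`` (e.g.
    L1HS, L1PA2) is optional and filled in by subfamily annotation.
    """

    interval: GenomicInterval
    category: str
    uid: str
    subfamily: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length


def union_overlap_len(start: int, end: int, intervals: Iterable[tuple[int, int]]) -> int:
    """Bases of [start, end) covered by the union of ``intervals``.

    Intervals may overlap each other; shared bases are counted once.
    """
    clipped = sorted(
        (max(start, s), min(end, e)) for s, e in intervals if s < end and e > start
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered
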