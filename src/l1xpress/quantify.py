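"""Split-aware coverage and length-weighted normalized L1 expression.

Coverage follows the bedgraph model: every declared sequence is tiled by
ordered, non-overlapping intervals of constant integer depth, zero-depth
intervals included, with depth counted per aligned block (spliced
alignments contribute no coverage across intron skips, and deletions
leave gaps too).

Per-locus expression is the mean of the depths of the coverage intervals
overlapping the locus (the interval mean — each bedgraph segment counts
once regardless of width), normalized to reads-per-million of the sample.
The category summary is the length-weighted average of normalized values
across *all* reference loci of the category:

    weighted_avg_i = sum_r (norm_r * len_r) / sum_r len_r

so loci silenced or removed by filtering still dilute the average through
their lengths.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .alignment_filter import AlignmentRecord, blocks_of, coverage_blocks
from .intervals import L1Region


@dataclass
class CoverageTrack:
    """Bedgraph-model depth track.

    ``intervals[chrom]`` is a list of (start, end, depth) tuples tiling
    [0, length) exactly once, adjacent tuples having different depths.
    """

    seq_lengths: dict[str, int]
    intervals: dict[str, list[tuple[int, int, int]]]

    def chrom_starts(self, chrom: str) -> list[int]:
        return [s for s, _, _ in self.intervals[chrom]]


@dataclass
class LocusExpression:
    region: L1Region
    n_reads: int
    mean_cov: float
    normalized: float


@dataclass
class CategorySummary:
    category: str
    weighted_average: float
    n_loci: int
    n_expressed_loci: int


@dataclass
class SubfamilyReport:
    """Expressed-locus counts per subfamily among one category's loci."""

    counts: dict[str, int]
    percentages: dict[str, float]
    n_expressed: int


def genome_coverage(
    alns: Iterable[AlignmentRecord], declared_seqs: Mapping[str, int]
) -> CoverageTrack:
    """Per-base depth of aligned read bases over the declared sequences.

    Depth at base b is the number of aligned {M, =, X} runs covering b;
    both intron skips (N) and deletions (D) leave gaps, matching bedgraph
    tracks computed from BAM alignment blocks. Zero intervals are
    emitted. Sweep over block edges, so runtime scales with alignments,
    not genome size.
    """
    events: dict[str, dict[int, int]] = {name: {} for name in declared_seqs}
    for aln in alns:
        if aln.chrom not in declared_seqs:
            raise ValueError(f"alignment on undeclared sequence {aln.chrom!r}")
        span = blocks_of(aln).span
        if span.end > declared_seqs[aln.chrom]:
            raise ValueError(
                f"alignment of {aln.read_id} extends beyond {aln.chrom} "
                f"({span.end} > {declared_seqs[aln.chrom]})"
            )
        ev = events[aln.chrom]
        for block in coverage_blocks(aln):
            ev[block.start] = ev.get(block.start, 0) + 1
            ev[block.end] = ev.get(block.end, 0) - 1
    intervals: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, length in declared_seqs.items():
        ev = events[chrom]
        edges = sorted(p for p in ev if 0 < p < length)
        tiles: list[tuple[int, int, int]] = []
        depth = ev.get(0, 0)
        prev = 0
        for pos in edges:
            if pos > prev:
                if tiles and tiles[-1][2] == depth:
                    tiles[-1] = (tiles[-1][0], pos, depth)
                else:
                    tiles.append((prev, pos, depth))
            depth += ev[pos]
            prev = pos
        if length > prev:
            if tiles and tiles[-1][2] == depth:
                tiles[-1] = (tiles[-1][0], length, depth)
            else:
                tiles.append((prev, length, depth))
        intervals[chrom] = tiles
    return CoverageTrack(seq_lengths=dict(declared_seqs), intervals=intervals)


def mean_coverage(
    track: CoverageTrack, region: L1Region, mode: str = "interval_mean"
) -> float:
    """Mean depth over a locus.

    ``interval_mean`` — unweighted arithmetic mean of the depth values of
    the track intervals overlapping the region (each bedgraph segment
    counts once, however wide). ``base_mean`` — per-base average depth
    over the region. The two differ whenever overlapping segments have
    unequal widths.
    """
    if region.chrom not in track.intervals:
        raise KeyError(f"sequence {region.chrom!r} absent from coverage track")
    tiles = track.intervals[region.chrom]
    starts = [s for s, _, _ in tiles]
    i = bisect.bisect_right(starts, region.start) - 1
    i = max(i, 0)
    depths: list[int] = []
    weighted = 0
    for s, e, d in tiles[i:]:
        if s >= region.end:
            break
        if e <= region.start:
            continue
        depths.append(d)
        weighted += d * (min(e, region.end) - max(s, region.start))
    if mode == "interval_mean":
        return sum(depths) / len(depths) if depths else 0.0
    if mode == "base_mean":
        return weighted / region.length
    raise ValueError(f"unknown mode {mode!r}")


def normalize(mean_cov: float, total_reads: int, scale: float = 1e6) -> float:
    """Reads-per-million style normalization: mean_cov / total_reads * scale."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return mean_cov / total_reads * scale


def weighted_average(
    loci: Sequence[LocusExpression], expressed_only: bool = False
) -> CategorySummary:
    """Length-weighted mean of normalized expression for one category.

    All reference loci of the category contribute their lengths to the
    denominator (filtered-out loci carry normalized = 0); with
    ``expressed_only`` the average is restricted to loci with
    normalized > 0.
    """
    if not loci:
        raise ValueError("weighted_average of empty locus list")
    categories = {le.region.category for le in loci}
    if len(categories) != 1:
        raise ValueError(f"loci span multiple categories: {sorted(categories)}")
    pool = [le for le in loci if le.normalized > 0] if expressed_only else list(loci)
    n_expressed = sum(1 for le in loci if le.normalized > 0)
    if not pool:
        return CategorySummary(categories.pop(), 0.0, len(loci), 0)
    num = sum(le.normalized * le.region.length for le in pool)
    den = sum(le.region.length for le in pool)
    return CategorySummary(categories.pop(), num / den, len(loci), n_expressed)


def subfamily_report(loci: Sequence[LocusExpression]) -> SubfamilyReport:
    """Expressed-locus counts per subfamily (unset subfamily -> 'other')."""
    counts: dict[str, int] = {}
    for le in loci:
        if le.normalized > 0:
            name = le.region.subfamily or "other"
            counts[name] = counts.get(name, 0) + 1
    total = sum(counts.values())
    pct = {k: (100.0 * v / total if total else 0.0) for k, v in counts.items()}
    return SubfamilyReport(counts=counts, percentages=pct, n_expressed=total)


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------


def write_bedgraph(track: CoverageTrack, path) -> None:
    """4-column bedGraph, zero-depth intervals included."""
    with open(path, "w") as fh:
        for chrom in track.intervals:
            for s, e, d in track.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")


def write_locus_tsv(loci: Sequence[LocusExpression], path) -> None:
    with open(path, "w") as fh:
        fh.write("uid\tcategory\tsubfamily\tchrom\tstart\tend\tn_reads\tmean_cov\tnormalized\n")
        for le in loci:
            fh.write(
                f"{le.region.uid}\t{le.region.category}\t{le.region.subfamily or ''}\t"
                f"{le.region.chrom}\t{le.region.start}\t{le.region.end}\t"
                f"{le.n_reads}\t{le.mean_cov:.6g}\t{le.normalized:.6g}\n"
            )


def write_summary_tsv(summaries: Sequence[CategorySummary], path, header_note: str = "") -> None:
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        fh.write("category\tweighted_average\tn_loci\tn_expressed_loci\n")
        for s in summaries:
            fh.write(f"{s.category}\t{s.weighted_average:.6g}\t{s.n_loci}\t{s.n_expressed_loci}\n")


def write_subfamily_tsv(report: SubfamilyReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("subfamily\tn_expressed\tpercent\n")
        for name in sorted(report.counts):
            fh.write(f"{name}\t{report.counts[name]}\t{report.percentages[name]:.4g}\n")
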