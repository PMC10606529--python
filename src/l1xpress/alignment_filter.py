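"""Primary-alignment parsing, reference-block geometry, and the 90%
L1-containment read filter.

A read is retained only when at least 90% of its aligned reference span
falls inside the union of the L1 reference loci — this keeps reads
primarily transcribed from L1 elements and discards reads that merely
brush a locus. Each kept read is assigned the single locus with the
largest span overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pysam
from intervaltree import IntervalTree

from .intervals import GenomicInterval, L1Region, union_overlap_len

PathLike = Union[str, Path]

# CIGAR op codes (pysam numbering)
_MATCH_OPS = {0, 7, 8}  # M, =, X
_REF_CONSUME_BLOCK = {0, 2, 7, 8}  # M, D, =, X: reference-consuming, block-forming
_REF_SKIP = 3  # N: reference-consuming, splits blocks


@dataclass
class AlignmentRecord:
    """A primary genome alignment with its CIGAR geometry.

    ``start`` is the 0-based leftmost reference offset; ``cigar`` is the
    pysam (op, length) tuple list.
    """

    read_id: str
    chrom: str
    start: int
    cigar: list[tuple[int, int]]
    is_primary: bool = True
    mapq: int = 0


@dataclass
class AlignmentBlocks:
    """Reference geometry of one alignment.

    ``span`` runs from the alignment start to one past the rightmost
    reference-consuming base (N and D included); ``blocks`` are the
    maximal runs of {M, =, X, D} ops, split at N gaps — the bedgraph
    ``-split`` view of a spliced alignment.
    """

    span: GenomicInterval
    blocks: list[GenomicInterval]


def parse_alignments(path: PathLike) -> Iterator[AlignmentRecord]:
    """Stream mapped, primary, non-supplementary records from SAM/BAM.

    Coordinates arrive 0-based from pysam. Secondary and supplementary
    records — the aligner's alternative placements — are skipped, so each
    read contributes at most one record.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.cigartuples is None:
                raise ValueError(f"record {rec.query_name}: missing CIGAR")
            yield AlignmentRecord(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                start=rec.reference_start,
                cigar=list(rec.cigartuples),
                is_primary=True,
                mapq=rec.mapping_quality,
            )


def blocks_of(aln: AlignmentRecord) -> AlignmentBlocks:
    """Derive the reference span and N-split blocks of an alignment.

    S/H/I ops consume no reference; D is kept inside a block (a small
    deletion does not interrupt coverage); N (intron skip) closes the
    current block.
    """
    blocks: list[GenomicInterval] = []
    pos = aln.start
    block_start: Optional[int] = None
    for op, length in aln.cigar:
        if op in _REF_CONSUME_BLOCK:
            if block_start is None:
                block_start = pos
            pos += length
        elif op == _REF_SKIP:
            if block_start is not None:
                blocks.append(GenomicInterval(aln.chrom, block_start, pos))
                block_start = None
            pos += length
        # S, H, I, P: no reference advance
    if block_start is not None:
        blocks.append(GenomicInterval(aln.chrom, block_start, pos))
    if not blocks:
        raise ValueError(f"alignment of {aln.read_id} consumes no reference")
    span = GenomicInterval(aln.chrom, blocks[0].start, blocks[-1].end)
    return AlignmentBlocks(span=span, blocks=blocks)


def coverage_blocks(aln: AlignmentRecord) -> list[GenomicInterval]:
    """Aligned-base runs for depth computation: maximal {M, =, X} runs,
    split at both N and D.

    Deletions consume reference but align no read base, so they leave
    zero-coverage gaps — the depth semantics of bedgraph tracks computed
    from BAM blocks. Contrast :func:`blocks_of`, whose containment
    geometry keeps D inside a block.
    """
    blocks: list[GenomicInterval] = []
    pos = aln.start
    block_start: Optional[int] = None
    for op, length in aln.cigar:
        if op in _MATCH_OPS:
            if block_start is None:
                block_start = pos
            pos += length
        elif op in (2, _REF_SKIP):  # D or N both interrupt aligned bases
            if block_start is not None:
                blocks.append(GenomicInterval(aln.chrom, block_start, pos))
                block_start = None
            pos += length
    if block_start is not None:
        blocks.append(GenomicInterval(aln.chrom, block_start, pos))
    return blocks


def _region_tree(regions: Sequence[L1Region]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, region in enumerate(regions):
        trees.setdefault(region.chrom, IntervalTree()).addi(
            region.start, region.end, i
        )
    return trees


def containment_fraction(
    aln: AlignmentRecord,
    regions: Sequence[L1Region],
    trees: Optional[dict[str, IntervalTree]] = None,
    split: bool = False,
) -> float:
    """Fraction of the alignment's reference span inside the region union.

    The denominator is the full reference span (N and D included),
    mirroring an intersection-fraction test on the whole alignment
    interval; with ``split=True`` both numerator and denominator use the
    N-split blocks instead. Overlap is computed against the union of
    regions, so a read bridging two adjacent loci is not penalized.
    """
    geom = blocks_of(aln)
    if trees is None:
        trees = _region_tree(regions)
    tree = trees.get(aln.chrom)
    targets = geom.blocks if split else [geom.span]
    total = sum(iv.length for iv in targets)
    if total == 0:
        raise ValueError(f"alignment of {aln.read_id} has zero-length span")
    if tree is None:
        return 0.0
    covered = 0
    for iv in targets:
        hits = [(h.begin, h.end) for h in tree.overlap(iv.start, iv.end)]
        covered += union_overlap_len(iv.start, iv.end, hits)
    return covered / total


def assign_locus(
    aln: AlignmentRecord,
    regions: Sequence[L1Region],
    trees: Optional[dict[str, IntervalTree]] = None,
) -> Optional[L1Region]:
    """The region with the largest span overlap; ties break to the
    leftmost (smallest start, then uid) region. None when no overlap."""
    geom = blocks_of(aln)
    if trees is None:
        trees = _region_tree(regions)
    tree = trees.get(aln.chrom)
    if tree is None:
        return None
    best: Optional[L1Region] = None
    best_key: Optional[tuple] = None
    for hit in tree.overlap(geom.span.start, geom.span.end):
        region = regions[hit.data]
        ov = min(geom.span.end, hit.end) - max(geom.span.start, hit.begin)
        key = (-ov, region.start, region.uid)
        if best_key is None or key < best_key:
            best, best_key = region, key
    return best


def filter_by_containment(
    alns: Iterable[AlignmentRecord],
    regions: Sequence[L1Region],
    min_frac: float = 0.9,
    split: bool = False,
) -> Iterator[tuple[AlignmentRecord, L1Region]]:
    """Yield (alignment, assigned locus) for alignments contained in the
    L1 reference at >= ``min_frac`` (inclusive)."""
    trees = _region_tree(regions)
    for aln in alns:
        if containment_fraction(aln, regions, trees=trees, split=split) >= min_frac:
            locus = assign_locus(aln, regions, trees=trees)
            if locus is not None:
                yield aln, locus


def write_read_locus_table(
    pairs: Iterable[tuple[AlignmentRecord, L1Region]], path: PathLike
) -> int:
    """TSV of read_id, locus UID, category and alignment start (0-based)."""
    n = 0
    with open(path, "w") as fh:
        fh.write("read_id\tuid\tcategory\tchrom\tstart\n")
        for aln, locus in pairs:
            fh.write(f"{aln.read_id}\t{locus.uid}\t{locus.category}\t{aln.chrom}\t{aln.start}\n")
            n += 1
    return n
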