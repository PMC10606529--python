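"""Build pruned L1 category references and the custom LINE mapping library.

The L1Base2 database ships three BED files of full-length L1 loci: active
(intact ORF1+ORF2), inactive (full-length non-intact) and ORF2-only-intact.
Before quantification the references are pruned so that every retained
locus is specific and exon-free:

* active loci overlapping any inactive locus are removed whole;
* loci of every category overlapping an annotated exon are removed whole.

Removal is always whole-interval and strand-blind. The module also builds
the custom LINE library used to pre-select candidate reads (genomic LINE
copies longer than 4.5 kb from the RepeatMasker genome track, plus the
LINE consensus sequences) and annotates loci with the subfamily of the
best-overlapping track element.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

from intervaltree import IntervalTree

from .intervals import GenomicInterval, L1Region

PathLike = Union[str, Path]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class BedParseError(ValueError):
    """Raised for a malformed BED line; message names the line number."""


def _open_text(path: PathLike) -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def load_bed(path: PathLike) -> list[GenomicInterval]:
    """Parse a BED3/BED6 file into intervals, preserving order.

    Column 4 (name) and column 6 (strand) are honored when present.
    Raises :class:`BedParseError` for non-integer coordinates or
    start >= end, naming the offending line.
    """
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end or start < 0:
                raise BedParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = cols[3] if len(cols) > 3 else ""
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "."
            out.append(GenomicInterval(cols[0], start, end, strand=strand, name=name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    """Write intervals as BED6 (score column fixed at 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def load_l1_bed(path: PathLike, category: str) -> list[L1Region]:
    """Load an L1Base2 category BED; column 4 becomes the locus UID."""
    regions = []
    for i, iv in enumerate(load_bed(path)):
        uid = iv.name or f"{category}_{i + 1}"
        regions.append(L1Region(interval=iv, category=category, uid=uid))
    return regions


def extract_exons_from_gtf(path: PathLike) -> list[GenomicInterval]:
    """Exon intervals from a GTF (GENCODE dialect): rows with feature
    ``exon`` across all transcripts, unmerged, converted to 0-based
    half-open."""
    exons: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8 or cols[2] != "exon":
                continue
            start = int(cols[3]) - 1  # GTF is 1-based inclusive
            end = int(cols[4])
            strand = cols[6] if cols[6] in "+-" else "."
            exons.append(GenomicInterval(cols[0], start, end, strand=strand))
    return exons


def _build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def subtract_overlapping(
    primary: Sequence[GenomicInterval], blocking: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Keep every primary interval with zero overlapping bases against all
    blocking intervals.

    Whole-interval removal, never clipping: a single shared base discards
    the locus. Half-open abutment ([0,100) vs [100,150)) is not overlap.
    Strand-blind.
    """
    trees = _build_trees(blocking)
    kept = []
    for iv in primary:
        tree = trees.get(iv.chrom)
        if tree is None or not tree.overlaps(iv.start, iv.end):
            kept.append(iv)
    return kept


def exclude_exon_overlaps(
    regions: Sequence[L1Region], exons: Sequence[GenomicInterval]
) -> list[L1Region]:
    """Drop L1 regions sharing any base with an annotated exon (strand-blind)."""
    trees = _build_trees(exons)
    kept = []
    for region in regions:
        tree = trees.get(region.chrom)
        if tree is None or not tree.overlaps(region.start, region.end):
            kept.append(region)
    return kept


def prune_references(
    active: Sequence[L1Region],
    inactive: Sequence[L1Region],
    orf2: Sequence[L1Region],
    exons: Sequence[GenomicInterval],
) -> tuple[list[L1Region], list[L1Region], list[L1Region]]:
    """Full reference pruning.

    Active loci overlapping inactive loci are removed first; then all
    three categories are purged of exon overlaps. Inactive and ORF2
    references receive exon exclusion only.
    """
    inactive_ivs = [r.interval for r in inactive]
    active_kept_ivs = {
        id(iv) for iv in subtract_overlapping([r.interval for r in active], inactive_ivs)
    }
    active_pruned = [r for r in active if id(r.interval) in active_kept_ivs]
    return (
        exclude_exon_overlaps(active_pruned, exons),
        exclude_exon_overlaps(inactive, exons),
        exclude_exon_overlaps(orf2, exons),
    )


# ---------------------------------------------------------------------------
# RepeatMasker genome-track table (UCSC rmsk schema)
# ---------------------------------------------------------------------------


def load_rmsk_track(path: PathLike) -> list[dict]:
    """Read a UCSC RepeatMasker track TSV.

    Requires at least the columns genoName, genoStart, genoEnd, strand,
    repName, repClass (header row present; extra columns ignored).
    """
    rows = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = ("genoName", "genoStart", "genoEnd", "strand", "repName", "repClass")
        for col in required:
            if col not in idx:
                raise ValueError(f"{path}: missing rmsk column {col!r}")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < len(header):
                continue
            rows.append(
                {
                    "genoName": cols[idx["genoName"]],
                    "genoStart": int(cols[idx["genoStart"]]),
                    "genoEnd": int(cols[idx["genoEnd"]]),
                    "strand": cols[idx["strand"]],
                    "repName": cols[idx["repName"]],
                    "repClass": cols[idx["repClass"]],
                    "repFamily": cols[idx["repFamily"]] if "repFamily" in idx else "",
                }
            )
    return rows


def build_line_library(
    track_rows: Sequence[Mapping],
    consensus: Mapping[str, str],
    genome: Mapping[str, str],
    min_len: int = 4500,
) -> list[tuple[str, str, str]]:
    """Assemble the custom LINE mapping library.

    Returns (id, sequence, source) tuples: every genome-track row of
    repClass ``LINE`` spanning strictly more than ``min_len`` bases
    (sequence extracted from ``genome``, reverse-complemented on the -
    strand) followed by every consensus entry. ``genome`` may be a dict or
    a pyfaidx.Fasta; slices are converted with ``str``.
    """
    entries: list[tuple[str, str, str]] = []
    for row in track_rows:
        if row["repClass"] != "LINE":
            continue
        span = row["genoEnd"] - row["genoStart"]
        if span <= min_len:
            continue
        chrom = row["genoName"]
        if chrom not in genome:
            raise KeyError(f"sequence {chrom!r} absent from genome")
        seq = str(genome[chrom][row["genoStart"] : row["genoEnd"]]).upper()
        if row["strand"] == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        ident = f"{row['repName']}__{chrom}_{row['genoStart']}_{row['genoEnd']}"
        entries.append((ident, seq, "genome_track"))
    for name, seq in consensus.items():
        entries.append((name, str(seq).upper(), "consensus"))
    return entries


def write_library_fasta(entries: Iterable[tuple[str, str, str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for ident, seq, source in entries:
            fh.write(f">{ident} source={source}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def annotate_subfamily(
    regions: Sequence[L1Region],
    track_rows: Sequence[Mapping],
    min_len: int = 4500,
) -> list[L1Region]:
    """Assign each locus the repName of the best-overlapping long track row.

    Only track rows spanning strictly more than ``min_len`` bases compete.
    The winner has the largest base overlap; ties break to the
    lexicographically smallest repName. Loci with no overlap keep
    subfamily unset.
    """
    trees: dict[str, IntervalTree] = {}
    for row in track_rows:
        if row["genoEnd"] - row["genoStart"] <= min_len:
            continue
        trees.setdefault(row["genoName"], IntervalTree()).addi(
            row["genoStart"], row["genoEnd"], row["repName"]
        )
    out = []
    for region in regions:
        best: Optional[str] = None
        best_ov = 0
        tree = trees.get(region.chrom)
        if tree is not None:
            for hit in tree.overlap(region.start, region.end):
                ov = min(region.end, hit.end) - max(region.start, hit.begin)
                if ov > best_ov or (ov == best_ov and best is not None and hit.data < best):
                    best, best_ov = hit.data, ov
        out.append(
            L1Region(
                interval=region.interval,
                category=region.category,
                uid=region.uid,
                subfamily=best,
            )
        )
    return out
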