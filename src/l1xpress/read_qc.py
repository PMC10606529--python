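"""FASTQ/FASTA preprocessing: quality filter, length filter, conversion,
and read-length statistics.

Long reads are kept when their mean base quality reaches Q7 (the usual
basecaller pass threshold) and they are at least 1 kb long — shorter reads
cannot informatively cover a full-length ~6 kb L1 element. Mean read
quality follows the long-read convention: the Phred transform of the mean
per-base error probability, not the arithmetic mean of Q values.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

PathLike = Union[str, Path]


@dataclass
class ReadRecord:
    id: str
    sequence: str
    qualities: Optional[list[int]] = None  # per-base Phred scores

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError("qualities length must match sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadStats:
    n_reads: int
    n50: int
    median_len: float
    n_ge_1kb: int


def mean_read_q(read: ReadRecord) -> float:
    """Mean read quality: -10*log10 of the mean per-base error probability."""
    if read.qualities is None:
        raise ValueError(f"read {read.id}: qualities absent")
    if not read.qualities:
        raise ValueError(f"read {read.id}: empty read")
    mean_p = sum(10 ** (-q / 10) for q in read.qualities) / len(read.qualities)
    return -10 * math.log10(mean_p)


def filter_reads(
    reads: Iterable[ReadRecord], min_q: float = 7.0, min_len: int = 1000
) -> Iterator[ReadRecord]:
    """Keep reads with mean quality >= min_q and length >= min_len.

    The quality test is skipped for records without qualities (FASTA
    input). Order is preserved; filtering is idempotent.
    """
    for read in reads:
        if len(read) < min_len:
            continue
        if read.qualities is not None and mean_read_q(read) < min_q:
            continue
        yield read


def read_stats(lengths: Sequence[int]) -> ReadStats:
    """N50, median and >=1 kb count for a set of read lengths.

    N50 is the length at which the descending cumulative sum first reaches
    half the total bases. An empty input yields all-zero stats.
    """
    if not lengths:
        return ReadStats(0, 0, 0.0, 0)
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    n50 = ordered[-1]
    for length in ordered:
        acc += length
        if acc >= half:
            n50 = length
            break
    n = len(ordered)
    mid = n // 2
    if n % 2:
        median = float(ordered[mid])
    else:
        median = (ordered[mid - 1] + ordered[mid]) / 2
    return ReadStats(
        n_reads=n,
        n50=n50,
        median_len=median,
        n_ge_1kb=sum(1 for length in lengths if length >= 1000),
    )


# ---------------------------------------------------------------------------
# FASTQ/FASTA IO (Phred+33, gzip-transparent)
# ---------------------------------------------------------------------------


def _open_text(path: PathLike, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode.rstrip("t") or "r")


def parse_reads(path: PathLike) -> Iterator[ReadRecord]:
    """Stream reads from FASTA or FASTQ (extension-sniffed, .gz ok)."""
    from Bio import SeqIO

    name = str(path)
    if name.endswith(".gz"):
        stem = name[:-3]
    else:
        stem = name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            quals = rec.letter_annotations.get("phred_quality")
            yield ReadRecord(
                id=rec.id,
                sequence=str(rec.seq),
                qualities=list(quals) if quals is not None else None,
            )


def write_fasta(reads: Iterable[ReadRecord], path: PathLike) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for read in reads:
            fh.write(f">{read.id}\n")
            for i in range(0, len(read.sequence), 70):
                fh.write(read.sequence[i : i + 70] + "\n")
            n += 1
    return n


def write_fastq(reads: Iterable[ReadRecord], path: PathLike) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for read in reads:
            if read.qualities is None:
                raise ValueError(f"read {read.id}: cannot write FASTQ without qualities")
            qual = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


def write_stats_tsv(stats: ReadStats, sample: str, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tn_reads\tn50\tmedian_len\tn_ge_1kb\n")
        fh.write(
            f"{sample}\t{stats.n_reads}\t{stats.n50}\t{stats.median_len}\t{stats.n_ge_1kb}\n"
        )
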