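"""Shared fixtures and helpers: random alignment generation, BAM
round-tripping through pysam, and thin wrappers around the bedtools
oracle used for cross-validation."""

from __future__ import annotations

import random
import subprocess
from pathlib import Path

import pysam
import pytest

from l1xpress.alignment_filter import AlignmentRecord

# pysam op codes
M, I, D, N, S = 0, 1, 2, 3, 4


def random_cigar(rng: random.Random, max_block: int = 120) -> list[tuple[int, int]]:
    """A plausible long-read CIGAR: optional soft clips, M blocks broken by
    occasional I/D/N."""
    ops: list[tuple[int, int]] = []
    if rng.random() < 0.3:
        ops.append((S, rng.randint(1, 30)))
    n_blocks = rng.randint(1, 4)
    for b in range(n_blocks):
        ops.append((M, rng.randint(20, max_block)))
        if b < n_blocks - 1:
            gap_op = rng.choice([I, D, N])
            length = rng.randint(30, 400) if gap_op == N else rng.randint(1, 15)
            ops.append((gap_op, length))
    if rng.random() < 0.3:
        ops.append((S, rng.randint(1, 30)))
    return ops


def random_alignments(
    rng: random.Random, seqs: dict[str, int], n: int
) -> list[AlignmentRecord]:
    alns = []
    for i in range(n):
        chrom = rng.choice(list(seqs))
        cigar = random_cigar(rng)
        ref_len = sum(l for op, l in cigar if op in (M, D, N))
        start = rng.randint(0, max(0, seqs[chrom] - ref_len - 1))
        alns.append(AlignmentRecord(f"read{i}", chrom, start, cigar))
    return alns


def write_bam(alns: list[AlignmentRecord], seqs: dict[str, int], path: Path) -> Path:
    """Write records to a coordinate-sorted, indexed BAM."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": name, "LN": length} for name, length in seqs.items()],
    }
    ah = pysam.AlignmentHeader.from_dict(header)
    tids = {name: i for i, name in enumerate(seqs)}
    unsorted = str(path) + ".unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as fh:
        for a in alns:
            rec = pysam.AlignedSegment(ah)
            rec.query_name = a.read_id
            rec.reference_id = tids[a.chrom]
            rec.reference_start = a.start
            rec.cigartuples = a.cigar
            qlen = sum(l for op, l in a.cigar if op in (M, I, S))
            rec.query_sequence = "A" * qlen
            rec.flag = 0
            rec.mapping_quality = 60
            fh.write(rec)
    pysam.sort("-o", str(path), unsorted)
    pysam.index(str(path))
    return path


def run_bedtools(args: list[str], **kw) -> str:
    proc = subprocess.run(["bedtools"] + args, capture_output=True, text=True, **kw)
    assert proc.returncode == 0, proc.stderr
    return proc.stdout


def parse_bedgraph(text: str) -> dict[str, list[tuple[int, int, int]]]:
    out: dict[str, list[tuple[int, int, int]]] = {}
    for line in text.strip().splitlines():
        chrom, s, e, d = line.split("\t")
        out.setdefault(chrom, []).append((int(s), int(e), int(float(d))))
    return out


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default simulator bundle plus its truth, shared by the suite."""
    from l1xpress import simulate as sim

    out = tmp_path_factory.mktemp("bundle")
    truth = sim.simulate(sim.default_config(7), out)
    return out, truth
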