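"""Ground-truthed synthetic fixtures for the whole pipeline.

The simulator builds a toy genome, L1 category references, exon
annotation, a repeat track, reads, their RepeatMasker ``.out``
annotation, and pre-computed splice-free alignments (SAM written directly
from the planted geometry, so no external aligner is needed). Reads are
planted at the 5' end of each locus plus a small jitter, mimicking
autonomous L1 transcription initiating at the promoter.

Every artifact filter of the pipeline gets at least one decoy locus or
read constructed to fail exactly that filter, and at least one
near-boundary case constructed to pass it. The expected fate of every
locus and read is recorded in a :class:`TruthTable` derived from the
configuration alone — never from running the pipeline — so end-to-end
tests can check truth recovery.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

from .intervals import GenomicInterval, L1Region

PathLike = Union[str, Path]

# Locus kinds and the pipeline stage at which their reads/locus die.
KIND_OK = "ok"
KIND_EXON_OVERLAP = "exon_overlap"          # pruned from reference (exon rule)
KIND_INACTIVE_OVERLAP = "inactive_overlap"  # active locus pruned (overlap rule)
KIND_LOW_SUPPORT = "low_support"            # < 2 reads
KIND_INCONSISTENT = "inconsistent_starts"   # a read start deviates > 100 bp
KIND_THREE_PRIME = "three_prime_start"      # modal start > 1.5 kb into locus
KIND_HIGH_DIV = "high_divergence"           # reads at div >= 10 -> deselected
KIND_SHORT_READS = "short_reads"            # reads < 1 kb -> QC drop
KIND_DIV_BOUNDARY = "div_boundary"          # div 9.9: kept
KIND_WINDOW_BOUNDARY = "start_window_boundary"    # deviation exactly 100: kept
KIND_OFFSET_BOUNDARY = "start_offset_boundary"    # modal offset exactly 1500: kept
KIND_CONTAIN_BOUNDARY = "containment_boundary"    # containment exactly 0.90: kept


@dataclass
class LocusSpec:
    """One planted L1 locus and its read-planting recipe."""

    uid: str
    category: str
    chrom: str
    start: int
    length: int
    strand: str
    subfamily: str
    planted_reads: int
    kind: str = KIND_OK
    start_jitter: int = 40       # max 5'-offset of planted read starts (bp)
    truncation_fraction: float = 0.3  # read length as fraction of locus length
    divergence: float = 4.0      # RepeatMasker div reported for the reads

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class SimulationConfig:
    seed: int
    genome: list[tuple[str, int]]
    loci: list[LocusSpec]
    # free-standing decoy reads (constructed in default_config)
    offtarget_reads: int = 1     # LINE/L1 reads mapping outside every locus
    sine_reads: int = 1          # reads whose only annotation is SINE/Alu
    low_quality_reads: int = 1   # mean Q below 7
    secondary_records: int = 1   # extra secondary SAM records (must be skipped)
    read_quality: int = 12       # constant per-base Q for ordinary reads
    low_quality_q: int = 4

    def validate(self) -> None:
        sizes = dict(self.genome)
        for spec in self.loci:
            if spec.chrom not in sizes:
                raise ValueError(f"locus {spec.uid}: unknown chrom {spec.chrom}")
            if spec.end > sizes[spec.chrom]:
                raise ValueError(f"locus {spec.uid} exceeds {spec.chrom} bounds")
            if spec.planted_reads < 0:
                raise ValueError(f"locus {spec.uid}: negative planted_reads")
            if not (0.0 <= spec.divergence <= 100.0):
                raise ValueError(f"locus {spec.uid}: divergence outside [0, 100]")


@dataclass
class PlantedRead:
    read_id: str
    chrom: str
    start: int          # 0-based alignment start
    length: int
    quality: int
    rm_rows: list[tuple[float, str, str]]  # (div, repeat_name, class/family)
    expected_stage: str  # 'pass' or first failing stage
    locus_uid: Optional[str] = None
    secondary_at: Optional[tuple[str, int]] = None  # extra secondary placement


@dataclass
class TruthTable:
    """Expected fate of every locus and read, derived from the config."""

    loci: dict[str, dict]   # uid -> {category, in_reference, reason, n_surviving}
    reads: dict[str, dict]  # read_id -> {expected_stage, locus_uid}
    total_reads_post_q: int

    def to_json(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"loci": self.loci, "reads": self.reads,
                 "total_reads_post_q": self.total_reads_post_q},
                fh, indent=1, sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: PathLike) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(loci=d["loci"], reads=d["reads"],
                   total_reads_post_q=d["total_reads_post_q"])


def default_config(seed: int = 0) -> SimulationConfig:
    """The standard fixture: 17 loci covering every decoy class and every
    near-boundary pass case, on a 3-sequence 200 kb toy genome."""
    L = 6000
    loci = [
        LocusSpec("ACT-1", "active", "chrA", 2000, L, "+", "L1HS", 4,
                  KIND_OK, start_jitter=40, truncation_fraction=0.3, divergence=3.0),
        LocusSpec("ACT-2", "active", "chrA", 12000, L, "+", "L1HS", 3,
                  KIND_OK, start_jitter=30, truncation_fraction=0.25, divergence=5.0),
        LocusSpec("ACT-3", "active", "chrA", 22000, L, "-", "L1PA2", 5,
                  KIND_OK, start_jitter=20, truncation_fraction=0.2, divergence=2.0),
        LocusSpec("ACT-4", "active", "chrA", 32000, L, "+", "L1PA3", 2,
                  KIND_DIV_BOUNDARY, start_jitter=0, truncation_fraction=0.5,
                  divergence=9.9),
        LocusSpec("ACT-5", "active", "chrA", 42000, L, "+", "L1HS", 1,
                  KIND_LOW_SUPPORT, start_jitter=0, truncation_fraction=0.3),
        LocusSpec("ACT-6", "active", "chrA", 52000, L, "+", "L1HS", 3,
                  KIND_INCONSISTENT, start_jitter=0, truncation_fraction=0.3),
        LocusSpec("ACT-7", "active", "chrA", 62000, L, "+", "L1HS", 3,
                  KIND_EXON_OVERLAP, start_jitter=10, truncation_fraction=0.3),
        LocusSpec("INA-1", "inactive", "chrB", 2000, L, "+", "L1PA4", 3,
                  KIND_OK, start_jitter=30, truncation_fraction=0.3),
        LocusSpec("INA-2", "inactive", "chrB", 12000, L, "+", "L1PA5", 2,
                  KIND_THREE_PRIME, start_jitter=0, truncation_fraction=0.25),
        LocusSpec("INA-3", "inactive", "chrB", 22000, L, "+", "L1PA4", 2,
                  KIND_OFFSET_BOUNDARY, start_jitter=0, truncation_fraction=0.25),
        LocusSpec("INA-4", "inactive", "chrB", 32000, L, "+", "L1PA6", 2,
                  KIND_HIGH_DIV, start_jitter=0, truncation_fraction=0.3,
                  divergence=10.0),
        LocusSpec("INA-5", "inactive", "chrB", 42000, L, "+", "L1PA7", 2,
                  KIND_SHORT_READS, start_jitter=0, truncation_fraction=0.15),
        LocusSpec("ORF-1", "orf2", "chrC", 2000, L, "+", "L1PA2", 3,
                  KIND_OK, start_jitter=25, truncation_fraction=0.3),
        LocusSpec("ORF-2", "orf2", "chrC", 12000, L, "+", "L1PA3", 3,
                  KIND_WINDOW_BOUNDARY, start_jitter=0, truncation_fraction=0.25),
        LocusSpec("ACT-8", "active", "chrC", 22000, L, "+", "L1HS", 2,
                  KIND_INACTIVE_OVERLAP, start_jitter=10, truncation_fraction=0.3),
        LocusSpec("INA-6", "inactive", "chrC", 27500, L, "+", "L1PA4", 2,
                  KIND_OK, start_jitter=20, truncation_fraction=0.3),
        LocusSpec("ACT-9", "active", "chrC", 36000, L, "+", "L1HS", 2,
                  KIND_CONTAIN_BOUNDARY, start_jitter=0, truncation_fraction=0.3),
    ]
    return SimulationConfig(
        seed=seed,
        genome=[("chrA", 70000), ("chrB", 70000), ("chrC", 60000)],
        loci=loci,
    )


def _plant_reads(cfg: SimulationConfig, rng: random.Random) -> list[PlantedRead]:
    reads: list[PlantedRead] = []
    for spec in cfg.loci:
        rlen = max(200, int(spec.length * spec.truncation_fraction))
        base_rows = [(spec.divergence, spec.subfamily, "LINE/L1")]
        if spec.kind == KIND_INCONSISTENT:
            starts = [spec.start, spec.start, spec.start + 150]
        elif spec.kind == KIND_WINDOW_BOUNDARY:
            starts = [spec.start, spec.start, spec.start + 100]
        elif spec.kind == KIND_THREE_PRIME:
            starts = [spec.start + 1600] * spec.planted_reads
        elif spec.kind == KIND_OFFSET_BOUNDARY:
            starts = [spec.start + 1500] * spec.planted_reads
        elif spec.kind == KIND_CONTAIN_BOUNDARY:
            # overlap rlen - 0.1*rlen bases of the locus: exactly 0.90
            hang = rlen // 10
            starts = [spec.start - hang] * spec.planted_reads
        else:
            starts = [
                spec.start + rng.randint(0, spec.start_jitter)
                for _ in range(spec.planted_reads)
            ]
        if spec.kind == KIND_SHORT_READS:
            rlen = 900  # below the 1 kb QC cut
        if spec.kind in (KIND_EXON_OVERLAP, KIND_INACTIVE_OVERLAP):
            stage = "containment"       # locus absent from pruned reference
        elif spec.kind == KIND_HIGH_DIV:
            stage = "divergence_selection"
        elif spec.kind == KIND_SHORT_READS:
            stage = "qc_length"
        elif spec.kind in (KIND_LOW_SUPPORT, KIND_INCONSISTENT, KIND_THREE_PRIME):
            stage = "locus_filter"
        else:
            stage = "pass"
        for i, start in enumerate(starts):
            rows = list(base_rows)
            if spec.uid == "ACT-1" and i == 0:
                # an old, diverged secondary annotation must not block selection
                rows.append((25.0, "L1MA4", "LINE/L1"))
            reads.append(
                PlantedRead(
                    read_id=f"{spec.uid}_r{i + 1}",
                    chrom=spec.chrom,
                    start=start,
                    length=rlen,
                    quality=cfg.read_quality,
                    rm_rows=rows,
                    expected_stage=stage,
                    locus_uid=spec.uid,
                )
            )
        if spec.kind == KIND_CONTAIN_BOUNDARY:
            # one extra read at containment 0.89: dies at the read filter
            hang = rlen - int(0.89 * rlen)
            reads.append(
                PlantedRead(
                    read_id=f"{spec.uid}_low",
                    chrom=spec.chrom,
                    start=spec.start - hang,
                    length=rlen,
                    quality=cfg.read_quality,
                    rm_rows=list(base_rows),
                    expected_stage="containment",
                    locus_uid=spec.uid,
                )
            )
    # free-standing decoy reads
    for i in range(cfg.offtarget_reads):
        reads.append(PlantedRead(
            read_id=f"offtarget_r{i + 1}", chrom="chrC", start=50000 + 2000 * i,
            length=1500, quality=cfg.read_quality,
            rm_rows=[(4.0, "L1HS", "LINE/L1")],
            expected_stage="containment"))
    for i in range(cfg.sine_reads):
        reads.append(PlantedRead(
            read_id=f"sine_r{i + 1}", chrom="chrB", start=2020,
            length=1500, quality=cfg.read_quality,
            rm_rows=[(1.0, "AluY", "SINE/Alu")],
            expected_stage="divergence_selection"))
    for i in range(cfg.low_quality_reads):
        reads.append(PlantedRead(
            read_id=f"lowq_r{i + 1}", chrom="chrA", start=12010,
            length=1500, quality=cfg.low_quality_q,
            rm_rows=[(3.0, "L1HS", "LINE/L1")],
            expected_stage="qc_quality"))
    if cfg.secondary_records and reads:
        reads[0].secondary_at = ("chrB", 60000)
    return reads


def _expected_truth(cfg: SimulationConfig, reads: Sequence[PlantedRead]) -> TruthTable:
    loci: dict[str, dict] = {}
    for spec in cfg.loci:
        in_ref = spec.kind not in (KIND_EXON_OVERLAP, KIND_INACTIVE_OVERLAP)
        if not in_ref:
            reason, surviving = "excluded_reference", 0
        elif spec.kind in (KIND_HIGH_DIV, KIND_SHORT_READS):
            reason, surviving = "too_few_reads", 0
        elif spec.kind == KIND_LOW_SUPPORT:
            reason, surviving = "too_few_reads", 0
        elif spec.kind == KIND_INCONSISTENT:
            reason, surviving = "inconsistent_starts", 0
        elif spec.kind == KIND_THREE_PRIME:
            reason, surviving = "start_too_far", 0
        else:
            reason, surviving = "ok", spec.planted_reads
        loci[spec.uid] = {
            "category": spec.category,
            "in_reference": in_ref,
            "reason": reason,
            "n_surviving": surviving,
        }
    read_truth = {
        r.read_id: {"expected_stage": r.expected_stage, "locus_uid": r.locus_uid}
        for r in reads
    }
    total_post_q = sum(1 for r in reads if r.quality >= 7)
    return TruthTable(loci=loci, reads=read_truth, total_reads_post_q=total_post_q)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _random_genome(cfg: SimulationConfig, rng: random.Random) -> dict[str, str]:
    return {
        name: "".join(rng.choice("ACGT") for _ in range(length))
        for name, length in cfg.genome
    }


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _write_beds(cfg: SimulationConfig, out: Path) -> None:
    by_cat: dict[str, list[LocusSpec]] = {"active": [], "inactive": [], "orf2": []}
    for spec in cfg.loci:
        by_cat[spec.category].append(spec)
    for cat, specs in by_cat.items():
        with open(out / f"{cat}.bed", "w") as fh:
            for s in specs:
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.uid}\t0\t{s.strand}\n")


def _write_exons(cfg: SimulationConfig, out: Path) -> None:
    with open(out / "exons.bed", "w") as fh:
        for spec in cfg.loci:
            if spec.kind == KIND_EXON_OVERLAP:
                fh.write(f"{spec.chrom}\t{spec.start + 100}\t{spec.start + 400}\texon\t0\t+\n")
        # a harmless exon far from every locus
        fh.write("chrB\t65000\t65400\texon\t0\t-\n")


def _write_rmsk_track(cfg: SimulationConfig, out: Path) -> None:
    cols = "genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\n"
    with open(out / "rmsk_track.tsv", "w") as fh:
        fh.write(cols)
        for spec in cfg.loci:
            fh.write(
                f"{spec.chrom}\t{spec.start}\t{spec.end}\t{spec.strand}\t"
                f"{spec.subfamily}\tLINE\tL1\n"
            )
        # library decoys: a SINE, a LINE at exactly 4500 (excluded), one at 4501
        fh.write("chrB\t52000\t58000\t+\tAluY\tSINE\tAlu\n")
        fh.write("chrB\t58000\t62500\t+\tL1MC1\tLINE\tL1\n")
        fh.write("chrB\t62600\t67101\t-\tL1MC2\tLINE\tL1\n")


def _write_consensus(rng: random.Random, out: Path) -> None:
    seqs = {
        name: "".join(rng.choice("ACGT") for _ in range(1200))
        for name in ("L1HS", "L1PA2")
    }
    _write_fasta(seqs, out / "consensus.fasta")


def _write_reads(reads: Sequence[PlantedRead], genome: dict[str, str], out: Path) -> None:
    with open(out / "reads.fastq", "w") as fh:
        for r in reads:
            seq = genome[r.chrom][r.start : r.start + r.length]
            qual = chr(r.quality + 33) * len(seq)
            fh.write(f"@{r.read_id}\n{seq}\n+\n{qual}\n")


def _write_rm_out(reads: Sequence[PlantedRead], out: Path) -> None:
    header = (
        "   SW   perc perc perc  query     position in query    matching"
        "  repeat        position in repeat\n"
        "score   div. del. ins.  sequence  begin endneg(left)   repeat"
        "  class/family  begin end (left) ID\n"
        "\n"
    )
    with open(out / "reads.rm.out", "w") as fh:
        fh.write(header)
        rid = 0
        for r in reads:
            for div, rep_name, rep_class in r.rm_rows:
                rid += 1
                fh.write(
                    f" 1500 {div:5.1f}  0.5  0.3  {r.read_id}  1 {r.length} "
                    f"(0) + {rep_name} {rep_class} 1 {r.length} (0) {rid}\n"
                )


def _write_sam(
    reads: Sequence[PlantedRead], genome: dict[str, str],
    cfg: SimulationConfig, out: Path,
) -> None:
    with open(out / "alignments.sam", "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in cfg.genome:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in reads:
            seq = genome[r.chrom][r.start : r.start + r.length]
            fh.write(
                f"{r.read_id}\t0\t{r.chrom}\t{r.start + 1}\t60\t{len(seq)}M\t"
                f"*\t0\t0\t{seq}\t*\n"
            )
            if r.secondary_at is not None:
                chrom2, pos2 = r.secondary_at
                fh.write(
                    f"{r.read_id}\t256\t{chrom2}\t{pos2 + 1}\t0\t{len(seq)}M\t"
                    f"*\t0\t0\t*\t*\n"
                )


def simulate(cfg: SimulationConfig, out_dir: PathLike) -> TruthTable:
    """Write the full fixture bundle to ``out_dir`` and return its truth.

    Deterministic: the same config (seed included) yields a byte-identical
    bundle. Files written: genome.fa, active/inactive/orf2.bed, exons.bed,
    rmsk_track.tsv, consensus.fasta, reads.fastq, reads.rm.out,
    alignments.sam, truth.json.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(cfg.seed)
    genome = _random_genome(cfg, rng)
    reads = _plant_reads(cfg, rng)
    truth = _expected_truth(cfg, reads)
    _write_fasta(genome, out / "genome.fa")
    _write_beds(cfg, out)
    _write_exons(cfg, out)
    _write_rmsk_track(cfg, out)
    _write_consensus(rng, out)
    _write_reads(reads, genome, out)
    _write_rm_out(reads, out)
    _write_sam(reads, genome, cfg, out)
    truth.to_json(out / "truth.json")
    return truth


def toy_l1_reference() -> tuple[
    list[L1Region], list[L1Region], list[L1Region], list[GenomicInterval]
]:
    """A fixed 30-region replica of the category-reference pruning inputs.

    Returns (active, inactive, orf2, exons). The layout exercises every
    pruning rule: active loci overlapping inactive loci (including a
    single-base overlap), exon overlaps on every category (including
    1-bp overlaps and exact abutments that must NOT count), and the
    asymmetry that inactive loci overlapping active ones are retained.

    Expected survivors (derivable by hand from the coordinates below):
    active 8 -> 4 (A1, A4, A5, A7), inactive 15 -> 11 (I5, I7, I10, I14
    removed), orf2 7 -> 4 (O1, O3, O5, O6).
    """

    def reg(cat: str, uid: str, chrom: str, start: int, end: int) -> L1Region:
        return L1Region(GenomicInterval(chrom, start, end, name=uid), cat, uid)

    active = [
        reg("active", "A1", "chr1", 1000, 7000),       # clean -> kept
        reg("active", "A2", "chr1", 10000, 16000),     # overlaps I1 -> removed
        reg("active", "A3", "chr1", 30000, 36000),     # overlaps exon E1 -> removed
        reg("active", "A4", "chr1", 40000, 46000),     # abuts I2 -> kept
        reg("active", "A5", "chr1", 60000, 66000),     # clean -> kept
        reg("active", "A6", "chr2", 1000, 7000),       # 1-bp overlap with I3 -> removed
        reg("active", "A7", "chr2", 20000, 26000),     # exon E2 abuts -> kept
        reg("active", "A8", "chr2", 30000, 36000),     # overlaps I4 and E3 -> removed
    ]
    inactive = [
        reg("inactive", "I1", "chr1", 15500, 21500),   # overlaps A2 but is kept
        reg("inactive", "I2", "chr1", 46000, 52000),
        reg("inactive", "I3", "chr2", 6999, 13000),
        reg("inactive", "I4", "chr2", 35000, 41000),
        reg("inactive", "I5", "chr1", 70000, 76000),   # exon E4 -> removed
        reg("inactive", "I6", "chr1", 80000, 86000),
        reg("inactive", "I7", "chr1", 90000, 96000),   # 1-bp exon E5 -> removed
        reg("inactive", "I8", "chr1", 100000, 106000),
        reg("inactive", "I9", "chr2", 50000, 56000),
        reg("inactive", "I10", "chr2", 60000, 66000),  # exon E6 inside -> removed
        reg("inactive", "I11", "chr2", 70000, 76000),
        reg("inactive", "I12", "chr2", 80000, 86000),
        reg("inactive", "I13", "chr2", 90000, 96000),
        reg("inactive", "I14", "chr1", 110000, 116000),  # exon E7 at start -> removed
        reg("inactive", "I15", "chr1", 120000, 126000),
    ]
    orf2 = [
        reg("orf2", "O1", "chr1", 130000, 136000),
        reg("orf2", "O2", "chr1", 140000, 146000),     # 1-bp exon E8 -> removed
        reg("orf2", "O3", "chr2", 100000, 106000),
        reg("orf2", "O4", "chr2", 110000, 116000),     # exon E9 -> removed
        reg("orf2", "O5", "chr2", 120000, 126000),
        reg("orf2", "O6", "chr1", 150000, 156000),
        reg("orf2", "O7", "chr1", 160000, 166000),     # exon E10 covers all -> removed
    ]
    exons = [
        GenomicInterval("chr1", 35900, 36200, name="E1"),
        GenomicInterval("chr2", 19000, 20000, name="E2"),   # abuts A7: no overlap
        GenomicInterval("chr2", 30100, 30200, name="E3"),
        GenomicInterval("chr1", 69900, 70100, name="E4"),
        GenomicInterval("chr1", 95999, 96300, name="E5"),
        GenomicInterval("chr2", 62000, 62100, name="E6"),
        GenomicInterval("chr1", 110000, 110050, name="E7"),
        GenomicInterval("chr1", 145999, 146100, name="E8"),
        GenomicInterval("chr2", 115000, 117000, name="E9"),
        GenomicInterval("chr1", 160000, 166000, name="E10"),
        GenomicInterval("chr2", 130000, 130200, name="E11"),  # hits nothing
    ]
    return active, inactive, orf2, exons


def verify_truth(truth: TruthTable, result) -> list[str]:
    """Compare a :class:`~l1xpress.pipeline.PipelineResult` against the
    truth table; returns a list of human-readable diffs (empty = pass)."""
    diffs: list[str] = []
    verdicts = {v.region.uid: v for v in result.verdicts}
    surviving = result.surviving_reads_per_locus
    for uid, exp in truth.loci.items():
        if not exp["in_reference"]:
            if uid in verdicts:
                diffs.append(f"{uid}: expected exclusion from reference, got verdict")
            continue
        v = verdicts.get(uid)
        reason = v.reason if v is not None else "too_few_reads"
        if reason != exp["reason"]:
            diffs.append(f"{uid}: reason {reason!r} != expected {exp['reason']!r}")
        got_n = surviving.get(uid, 0)
        if got_n != exp["n_surviving"]:
            diffs.append(
                f"{uid}: surviving reads {got_n} != expected {exp['n_surviving']}"
            )
    return diffs
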