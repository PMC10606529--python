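"""End-to-end pipeline: QC -> candidate selection -> containment ->
locus artifact filters -> quantification.

Stage order follows the analysis flow: reads are quality/length filtered,
candidates are selected by RepeatMasker L1 divergence, genome alignments
of the candidates are kept when >=90% contained in the pruned L1
reference, loci are screened by the artifact rules, and surviving reads
are turned into split-aware coverage and length-weighted normalized
expression per category.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import alignment_filter as af
from . import locus_filter as lf
from . import quantify as qt
from . import read_qc as rq
from . import reference_prep as rp
from . import repeatmasker_io as rm
from .intervals import L1Region

PathLike = Union[str, Path]


@dataclass
class PipelineConfig:
    """All thresholds, at their standard values.

    min_len (bp) and min_q (Phred) gate the input reads; max_div (%) is
    the RepeatMasker divergence cut for candidate reads; min_frac is the
    L1-containment fraction; min_reads, start_window (bp) and
    max_start_offset (bp) are the locus artifact rules; scale is the
    normalization constant (per-million).
    """

    min_len: int = 1000
    min_q: float = 7.0
    max_div: float = 10.0
    class_prefix: str = "LINE/L1"
    min_frac: float = 0.9
    split_containment: bool = False
    min_reads: int = 2
    start_window: int = 100
    max_start_offset: int = 1500
    strand_aware_start: bool = False
    trim_outlier_reads: bool = False
    mean_mode: str = "interval_mean"
    expressed_only: bool = False
    scale: float = 1e6
    total_reads: Optional[int] = None  # override the post-Q read total


@dataclass
class PipelineResult:
    stats: rq.ReadStats
    total_reads: int
    counts: dict[str, int]
    references: dict[str, list[L1Region]]
    verdicts: list[lf.LocusVerdict]
    surviving_reads_per_locus: dict[str, int]
    surviving_read_ids: set[str]
    coverage: qt.CoverageTrack
    expressions: dict[str, list[qt.LocusExpression]]
    summaries: dict[str, qt.CategorySummary]
    subfamilies: qt.SubfamilyReport


def load_references(
    active_bed: PathLike,
    inactive_bed: PathLike,
    orf2_bed: PathLike,
    exons: PathLike,
    rmsk_track: Optional[PathLike] = None,
) -> dict[str, list[L1Region]]:
    """Load and prune the three category references; optionally annotate
    subfamilies from a RepeatMasker genome-track table."""
    active = rp.load_l1_bed(active_bed, "active")
    inactive = rp.load_l1_bed(inactive_bed, "inactive")
    orf2 = rp.load_l1_bed(orf2_bed, "orf2")
    exon_path = str(exons)
    if exon_path.endswith((".gtf", ".gtf.gz", ".gff", ".gff.gz")):
        exon_ivs = rp.extract_exons_from_gtf(exons)
    else:
        exon_ivs = rp.load_bed(exons)
    active_p, inactive_p, orf2_p = rp.prune_references(active, inactive, orf2, exon_ivs)
    if rmsk_track is not None:
        rows = rp.load_rmsk_track(rmsk_track)
        active_p = rp.annotate_subfamily(active_p, rows)
        inactive_p = rp.annotate_subfamily(inactive_p, rows)
        orf2_p = rp.annotate_subfamily(orf2_p, rows)
    return {"active": active_p, "inactive": inactive_p, "orf2": orf2_p}


def run_all(
    reads_path: PathLike,
    rm_out_path: PathLike,
    alignments_path: PathLike,
    active_bed: PathLike,
    inactive_bed: PathLike,
    orf2_bed: PathLike,
    exons: PathLike,
    rmsk_track: Optional[PathLike] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    counts: dict[str, int] = {}

    # 1. read QC ------------------------------------------------------------
    reads = list(rq.parse_reads(reads_path))
    counts["input_reads"] = len(reads)
    q_passed = [
        r for r in reads
        if r.qualities is None or rq.mean_read_q(r) >= cfg.min_q
    ]
    counts["reads_post_q"] = len(q_passed)
    total_reads = cfg.total_reads if cfg.total_reads is not None else len(q_passed)
    qc_passed = [r for r in q_passed if len(r) >= cfg.min_len]
    counts["reads_post_length"] = len(qc_passed)
    stats = rq.read_stats([len(r) for r in qc_passed])
    qc_ids = {r.id for r in qc_passed}

    # 2. divergence selection ------------------------------------------------
    hits = rm.parse_rm_out(rm_out_path)
    selected = rm.select_reads_by_divergence(hits, cfg.max_div, cfg.class_prefix)
    candidate_ids = qc_ids & selected
    counts["reads_post_divergence"] = len(candidate_ids)

    # 3. reference pruning ---------------------------------------------------
    references = load_references(active_bed, inactive_bed, orf2_bed, exons, rmsk_track)
    all_regions: list[L1Region] = [
        r for cat in ("active", "inactive", "orf2") for r in references[cat]
    ]
    counts["reference_loci"] = len(all_regions)

    # 4. containment ---------------------------------------------------------
    alns = [
        a for a in af.parse_alignments(alignments_path) if a.read_id in candidate_ids
    ]
    counts["primary_alignments"] = len(alns)
    pairs = list(
        af.filter_by_containment(
            alns, all_regions, min_frac=cfg.min_frac, split=cfg.split_containment
        )
    )
    counts["reads_post_containment"] = len(pairs)

    # 5. locus artifact filters ----------------------------------------------
    grouped: dict[str, list[tuple[af.AlignmentRecord, L1Region]]] = defaultdict(list)
    for aln, locus in pairs:
        grouped[locus.uid].append((aln, locus))
    locus_sets = [
        lf.LocusReadSet(
            region=group[0][1],
            read_starts=[a.start for a, _ in group],
            read_ids=[a.read_id for a, _ in group],
        )
        for group in grouped.values()
    ]
    verdicts = lf.apply_locus_filters(
        locus_sets,
        min_reads=cfg.min_reads,
        start_window=cfg.start_window,
        max_start_offset=cfg.max_start_offset,
        strand_aware_start=cfg.strand_aware_start,
        trim_outlier_reads=cfg.trim_outlier_reads,
    )
    # reference loci that attracted no reads at all
    seen = set(grouped)
    for region in all_regions:
        if region.uid not in seen:
            verdicts.append(
                lf.LocusVerdict(region, 0, None, kept=False, reason=lf.REASON_TOO_FEW)
            )
    surviving_ids = lf.surviving_read_ids(locus_sets, verdicts)
    kept_uids = {v.region.uid for v in verdicts if v.kept}
    surviving_per_locus = {
        ls.region.uid: len([r for r in ls.read_ids if r in surviving_ids])
        for ls in locus_sets
        if ls.region.uid in kept_uids
    }
    counts["reads_post_locus_filter"] = len(surviving_ids)
    counts["loci_kept"] = len(kept_uids)

    # 6. quantification ------------------------------------------------------
    import pysam

    mode = "rb" if str(alignments_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(alignments_path), mode) as afh:
        declared = dict(zip(afh.references, afh.lengths))
    surviving_alns = [a for a in alns if a.read_id in surviving_ids]
    coverage = qt.genome_coverage(surviving_alns, declared)

    expressions: dict[str, list[qt.LocusExpression]] = {}
    summaries: dict[str, qt.CategorySummary] = {}
    for cat in ("active", "inactive", "orf2"):
        locs = []
        for region in references[cat]:
            mean = qt.mean_coverage(coverage, region, mode=cfg.mean_mode)
            locs.append(
                qt.LocusExpression(
                    region=region,
                    n_reads=surviving_per_locus.get(region.uid, 0),
                    mean_cov=mean,
                    normalized=qt.normalize(mean, total_reads, cfg.scale),
                )
            )
        expressions[cat] = locs
        if locs:
            summaries[cat] = qt.weighted_average(locs, expressed_only=cfg.expressed_only)
        else:
            summaries[cat] = qt.CategorySummary(cat, 0.0, 0, 0)
    subfamilies = qt.subfamily_report(expressions["active"])

    return PipelineResult(
        stats=stats,
        total_reads=total_reads,
        counts=counts,
        references=references,
        verdicts=verdicts,
        surviving_reads_per_locus=surviving_per_locus,
        surviving_read_ids=surviving_ids,
        coverage=coverage,
        expressions=expressions,
        summaries=summaries,
        subfamilies=subfamilies,
    )


def run_on_bundle(bundle_dir: PathLike, config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run the full pipeline on a simulator fixture bundle directory."""
    d = Path(bundle_dir)
    return run_all(
        reads_path=d / "reads.fastq",
        rm_out_path=d / "reads.rm.out",
        alignments_path=d / "alignments.sam",
        active_bed=d / "active.bed",
        inactive_bed=d / "inactive.bed",
        orf2_bed=d / "orf2.bed",
        exons=d / "exons.bed",
        rmsk_track=d / "rmsk_track.tsv",
        config=config,
    )


def write_outputs(result: PipelineResult, out_dir: PathLike) -> None:
    """Write every intermediate and summary table to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rq.write_stats_tsv(result.stats, "sample", out / "read_stats.tsv")
    lf.write_verdicts_tsv(result.verdicts, out / "locus_verdicts.tsv")
    qt.write_bedgraph(result.coverage, out / "coverage.bedgraph")
    all_loci = [le for cat in ("active", "inactive", "orf2") for le in result.expressions[cat]]
    qt.write_locus_tsv(all_loci, out / "locus_expression.tsv")
    qt.write_summary_tsv(
        list(result.summaries.values()),
        out / "category_summary.tsv",
        header_note=f"normalization total_reads={result.total_reads} scale=1e6",
    )
    qt.write_subfamily_tsv(result.subfamilies, out / "subfamily_report.tsv")
    with open(out / "stage_counts.tsv", "w") as fh:
        fh.write("stage\tcount\n")
        for stage, count in result.counts.items():
            fh.write(f"{stage}\t{count}\n")
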