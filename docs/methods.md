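# Methods

## Problem and model

LINE-1 (L1) is an autonomous ~6 kb human retrotransposon. Only a small
set of young, full-length genomic copies — chiefly the L1HS and L1PA2
subfamilies — retain intact open reading frames and transcribe
autonomously from their 5' promoter. Measuring which individual loci are
expressed is hard with short reads because L1 copies are highly similar;
long reads can span enough unique flanking context to support
locus-level assignment, but repeat-derived alignments remain artifact
prone. `l1xpress` quantifies locus-specific expression of young
full-length L1s from long-read RNA-seq by combining candidate-read
selection, a containment filter, and locus-level artifact screens, then
summarizing expression per L1 category.

The reference model is the L1Base2 categorization of full-length L1
loci: **active** (intact ORF1 and ORF2), **inactive** (full-length,
non-intact) and **orf2** (intact only in ORF2). Coordinates are 0-based
half-open everywhere internally; BED input maps directly, SAM and GTF
are converted at parse time.

## Pipeline stages and parameters

1. **Read QC** — keep reads with mean quality ≥ `min_q` (default Q7) and
   length ≥ `min_len` (default 1000 bp; shorter reads are uninformative
   for ~6 kb elements). Mean read quality is the Phred transform of the
   mean per-base error probability (the long-read basecaller
   convention), not the arithmetic mean of Q values. The per-sample read
   total used for normalization is the count of reads passing the
   quality filter — the earliest per-sample total the pipeline sees —
   overridable via `total_reads`.
2. **Candidate selection** — a read qualifies when any of its
   RepeatMasker annotations has class/family starting with `LINE/L1` and
   `div` strictly below `max_div` (default 10%). The strict inequality
   follows the threshold's definition; divergence is a proxy for element
   age, so the cut restricts analysis to young elements. Class matching
   is by prefix so subfamily-qualified values match.
3. **Reference pruning** — active loci overlapping any inactive locus
   are removed whole (never clipped), then loci of every category
   overlapping an annotated exon are removed whole. Overlap is
   strand-blind and a single shared base counts; half-open abutment does
   not. Pruning is asymmetric: inactive loci overlapping active ones are
   retained. Exons are taken from GTF rows with feature `exon` across
   all transcripts, unmerged, or from a BED.
4. **Containment** — only mapped, primary, non-supplementary alignments
   are considered. An alignment is kept when ≥ `min_frac` (default 0.9,
   inclusive) of its reference span lies in the union of reference loci.
   The denominator is the full span including intron skips (N) and
   deletions (D), mirroring an interval-intersection test on the whole
   alignment; `split_containment` switches both sides to N-split blocks.
   Using the union means a read bridging two abutting loci is not
   penalized; the external interval-intersection tools compute per-region
   fractions instead, so the two differ only for such bridging reads
   (the cross-validation fixtures space loci apart to stay in the regime
   where they provably coincide). Each kept read is assigned the locus
   with the largest span overlap; ties break to the leftmost locus.
5. **Locus artifact screens**, in order: (i) fewer than `min_reads`
   (default 2) assigned reads removes the locus; (ii) any read start
   more than `start_window` (default 100 bp) from the locus's most
   common start removes the locus (genuine promoter-driven transcription
   clusters read starts; `trim_outlier_reads` drops outlier reads
   instead); (iii) a modal start more than `max_start_offset` (default
   1500 bp) from the reference start removes the locus (starts deep in
   the element suggest read-through rather than autonomous
   transcription). All thresholds are inclusive on the keep side. The
   modal start breaks frequency ties toward the smaller coordinate. The
   "reference start" is the lower genomic coordinate regardless of
   strand by default, matching coordinate-based interval tooling;
   `strand_aware_start` measures from the biological 5' end instead
   (BED end for minus-strand loci). Loci that attracted no reads at all
   are recorded with the same too-few-reads verdict.
6. **Quantification** — coverage of the surviving reads follows the
   bedgraph model: each sequence is tiled by constant-depth intervals,
   zeros included, depth counted per aligned {M,=,X} run (both N and D
   leave gaps — verified bit-exact against interval-tool output).
   Per-locus `mean_cov` is by default the unweighted mean of the depth
   values of the tiles overlapping the locus (each tile counts once,
   however wide — the semantics of mapping a column mean over a bedgraph);
   `mean_mode="base_mean"` gives the per-base average instead, because
   the two differ whenever tile widths are skewed. Normalization is
   `mean_cov / total_reads × 10^6`. The category summary is the
   length-weighted average of normalized values across **all** reference
   loci of the category — silenced or filtered loci contribute zero at
   full length, diluting the average — with `expressed_only` restricting
   to loci with nonzero expression. The subfamily report counts
   expressed active loci per subfamily; subfamily is the repName of the
   best-overlapping repeat-track element longer than 4.5 kb (largest
   overlap, ties to the lexicographically smallest name).

The custom LINE mapping library combines genomic LINE copies spanning
strictly more than 4500 bp from a RepeatMasker genome-track table
(minus-strand sequences reverse-complemented) with the supplied LINE
consensus FASTA. The strict cut reads "greater than 4.5 kb" literally.

## Synthetic data

The simulator emits a complete fixture bundle — toy genome (3 sequences,
200 kb total), category BEDs, exon BED, repeat track, FASTQ, RepeatMasker
`.out`, SAM — with reads planted at each locus's 5' end plus bounded
jitter and truncated to a fraction of the locus, emulating
promoter-proximal starts of autonomous L1 transcription. Alignments are
written directly from the planted geometry (all-match CIGARs over exact
genome substrings), so no aligner runs and alignment is error-free by
construction. The default configuration has 17 loci: one decoy per
filter rule (exon overlap, active-over-inactive overlap, single-read
support, inconsistent starts, 3'-biased starts, ≥10% divergence,
sub-1 kb reads) and one near-boundary pass case per thresholded rule
(divergence 9.9, start deviation exactly 100 bp, modal offset exactly
1500 bp, containment exactly 0.90), plus free-standing decoy reads
(off-target, SINE-annotated, low-quality, a secondary alignment record).
The truth table is derived from the configuration alone, never from the
pipeline.

What the simulator does **not** model: sequencing errors and indels,
splicing, quality-score variation within reads, multi-mapping ambiguity
between near-identical L1 copies, and polymorphic non-reference
insertions. Passing truth-recovery therefore demonstrates that the
filter logic and bookkeeping are correct, not that locus assignment is
robust to real long-read error profiles — that robustness comes from the
thresholds themselves, which the tests exercise only at their
boundaries.

## Numerical choices and degenerate inputs

* Coverage is computed by an event sweep over block edges, so memory
  scales with alignments rather than genome size; depths are exact
  integers and the bedgraph comparison against the external oracle is
  bit-exact.
* Interval means are exact rational sums over small integers divided
  once; the oracle comparison allows 1e-9 or bit-identity at the
  oracle's 10-significant-digit printed precision.
* Empty inputs: empty BEDs give empty references; an empty length list
  gives all-zero read statistics; a category with no reference loci
  reports a zero summary; `weighted_average` of an empty locus list,
  `modal_start` of an empty list, normalization with a zero read total,
  and mean quality of a read without qualities are errors.
* Tie-breaks are all deterministic and documented at the definition
  site: modal start → smaller coordinate; locus assignment → larger
  overlap then leftmost; subfamily → larger overlap then lexicographic.
* Problem sizes: cross-validation fixtures use ≤ 30 alignments over two
  short sequences, 100 fixtures per run; truth recovery uses 20 seeds of
  the 17-locus bundle (~48 reads each). These sizes exercise every code
  path and keep the whole verification run under a few seconds.

## Known limitations

* Locus assignment trusts the aligner's primary placement; no
  multi-mapping resolution or MAPQ screen is applied beyond
  primary-only.
* The containment union semantics diverge from per-region
  interval-intersection for reads bridging adjacent loci (see stage 4).
* The interval-mean default inherits the width-blindness of averaging
  bedgraph tiles; `base_mean` is provided where per-base averages are
  wanted.
* Category averages are comparable across samples only under the same
  `total_reads` convention; the convention used is recorded in the
  summary header.
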