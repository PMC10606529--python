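"""Coverage track construction, per-locus means, normalization and the
length-weighted category average."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from l1xpress import quantify as qt
from l1xpress.alignment_filter import AlignmentRecord, coverage_blocks
from l1xpress.intervals import GenomicInterval, L1Region

M, D, N = 0, 2, 3


def aln(start, cigar, chrom="chr1", rid="r"):
    return AlignmentRecord(rid, chrom, start, cigar)


def region(start, end, uid="u", chrom="chr1", category="active", subfamily=None):
    return L1Region(GenomicInterval(chrom, start, end, name=uid), category, uid,
                    subfamily=subfamily)


def expr(length, normalized, uid="u", category="active", subfamily=None):
    return qt.LocusExpression(
        region=region(0, length, uid=uid, category=category, subfamily=subfamily),
        n_reads=0, mean_cov=0.0, normalized=normalized)


class TestGenomeCoverage:
    def test_spliced_read(self):
        track = qt.genome_coverage([aln(100, [(M, 50), (N, 1000), (M, 50)])],
                                   {"chr1": 2000})
        assert track.intervals["chr1"] == [
            (0, 100, 0), (100, 150, 1), (150, 1150, 0), (1150, 1200, 1), (1200, 2000, 0)]

    def test_two_identical_reads_double_depth(self):
        a = aln(100, [(M, 50), (N, 1000), (M, 50)])
        single = qt.genome_coverage([a], {"chr1": 2000})
        double = qt.genome_coverage([a, a], {"chr1": 2000})
        assert [(s, e) for s, e, _ in double.intervals["chr1"]] == [
            (s, e) for s, e, _ in single.intervals["chr1"]]
        assert [d for *_, d in double.intervals["chr1"]] == [
            2 * d for *_, d in single.intervals["chr1"]]

    def test_no_reads_single_zero_interval(self):
        track = qt.genome_coverage([], {"chr1": 500, "chr2": 80})
        assert track.intervals == {"chr1": [(0, 500, 0)], "chr2": [(0, 80, 0)]}

    def test_deletion_leaves_gap(self):
        # only aligned read bases carry depth: a 3-bp deletion is uncovered
        track = qt.genome_coverage([aln(10, [(M, 5), (D, 3), (M, 5)])], {"chr1": 30})
        assert track.intervals["chr1"] == [
            (0, 10, 0), (10, 15, 1), (15, 18, 0), (18, 23, 1), (23, 30, 0)]

    def test_out_of_bounds_alignment_errors(self):
        with pytest.raises(ValueError):
            qt.genome_coverage([aln(90, [(M, 20)])], {"chr1": 100})

    def test_track_tiles_sequences_with_depth_changes(self):
        rng = random.Random(2)
        alns = [aln(rng.randint(0, 800), [(M, rng.randint(10, 150))], rid=f"r{i}")
                for i in range(25)]
        track = qt.genome_coverage(alns, {"chr1": 1000})
        tiles = track.intervals["chr1"]
        assert tiles[0][0] == 0 and tiles[-1][1] == 1000
        for (s1, e1, d1), (s2, e2, d2) in zip(tiles, tiles[1:]):
            assert e1 == s2 and d1 != d2

    def test_coverage_conservation(self):
        rng = random.Random(9)
        alns = []
        for i in range(40):
            cigar = [(M, rng.randint(10, 100))]
            if rng.random() < 0.5:
                cigar += [(N, rng.randint(20, 200)), (M, rng.randint(10, 100))]
            alns.append(aln(rng.randint(0, 2000), cigar, rid=f"r{i}"))
        track = qt.genome_coverage(alns, {"chr1": 4000})
        mass = sum(d * (e - s) for s, e, d in track.intervals["chr1"])
        block_mass = sum(b.length for a in alns for b in coverage_blocks(a))
        assert mass == block_mass


class TestMeanCoverage:
    def track(self, tiles, length):
        return qt.CoverageTrack({"chr1": length}, {"chr1": tiles})

    def test_interval_mean_vs_base_mean_agree_on_balanced_split(self):
        track = self.track([(0, 10, 0), (10, 20, 5)], 20)
        reg = region(5, 15)
        assert qt.mean_coverage(track, reg) == pytest.approx(2.5)
        assert qt.mean_coverage(track, reg, mode="base_mean") == pytest.approx(2.5)

    def test_modes_differ_on_skewed_intervals(self):
        track = self.track([(0, 90, 0), (90, 100, 9)], 100)
        reg = region(0, 100)
        assert qt.mean_coverage(track, reg) == pytest.approx(4.5)
        assert qt.mean_coverage(track, reg, mode="base_mean") == pytest.approx(0.9)

    def test_constant_depth_identical_in_both_modes(self):
        track = self.track([(0, 50, 0), (50, 250, 3), (250, 400, 0)], 400)
        reg = region(100, 200)
        assert qt.mean_coverage(track, reg) == 3.0
        assert qt.mean_coverage(track, reg, mode="base_mean") == 3.0

    def test_absent_chrom_errors(self):
        track = self.track([(0, 10, 0)], 10)
        with pytest.raises(KeyError):
            qt.mean_coverage(track, region(0, 5, chrom="chrX"))


class TestNormalize:
    def test_identity_at_one_million(self):
        assert qt.normalize(2.0, 1_000_000) == pytest.approx(2.0)

    def test_zero_coverage(self):
        assert qt.normalize(0.0, 10) == 0.0

    def test_scaling(self):
        assert qt.normalize(3.0, 500_000) == pytest.approx(6.0)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            qt.normalize(1.0, 0)


class TestWeightedAverage:
    def test_worked_example(self):
        loci = [expr(6000, 2.0, "a"), expr(4000, 0.5, "b")]
        assert qt.weighted_average(loci).weighted_average == pytest.approx(1.4)

    def test_constant_values_invariant(self):
        loci = [expr(l, 3.7, uid=f"u{l}") for l in (1000, 2000, 5000)]
        assert qt.weighted_average(loci).weighted_average == pytest.approx(3.7)

    def test_zero_locus_dilution(self):
        loci = [expr(5000, 10.0, "hot")] + [expr(5000, 0.0, f"z{i}") for i in range(9)]
        s = qt.weighted_average(loci)
        assert s.weighted_average == pytest.approx(1.0)
        assert s.n_expressed_loci == 1

    def test_expressed_only_mode_skips_silent_loci(self):
        loci = [expr(5000, 10.0, "hot")] + [expr(5000, 0.0, f"z{i}") for i in range(9)]
        assert qt.weighted_average(loci, expressed_only=True).weighted_average == \
            pytest.approx(10.0)

    def test_result_within_contributing_range(self):
        rng = random.Random(4)
        loci = [expr(rng.randint(1000, 8000), rng.uniform(0, 5), uid=f"u{i}")
                for i in range(20)]
        wa = qt.weighted_average(loci).weighted_average
        values = [le.normalized for le in loci]
        assert min(values) <= wa <= max(values)

    def test_mixed_categories_rejected(self):
        loci = [expr(1000, 1.0, "a"), expr(1000, 1.0, "b", category="orf2")]
        with pytest.raises(ValueError):
            qt.weighted_average(loci)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            qt.weighted_average([])


class TestSubfamilyReport:
    def test_counts_and_percentages(self):
        loci = [expr(6000, 1.0, f"h{i}", subfamily="L1HS") for i in range(3)]
        loci += [expr(6000, 2.0, "p", subfamily="L1PA2")]
        loci += [expr(6000, 0.0, "silent", subfamily="L1HS")]
        rep = qt.subfamily_report(loci)
        assert rep.counts == {"L1HS": 3, "L1PA2": 1}
        assert rep.percentages["L1HS"] == pytest.approx(75.0)
        assert rep.percentages["L1PA2"] == pytest.approx(25.0)

    def test_no_expression(self):
        rep = qt.subfamily_report([expr(6000, 0.0, "s", subfamily="L1HS")])
        assert rep.counts == {} and rep.n_expressed == 0

    def test_unset_subfamily_counts_as_other(self):
        rep = qt.subfamily_report([expr(6000, 1.0, "x")])
        assert rep.counts == {"other": 1}


@settings(max_examples=60, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_duplicating_reads_doubles_means_and_preserves_ratios(seed):
    """Pipeline linearity: doubling every input read doubles every locus
    mean; after re-normalizing by the doubled total, category averages are
    unchanged."""
    rng = random.Random(seed)
    alns = [aln(rng.randint(0, 900), [(M, rng.randint(20, 90))], rid=f"r{i}")
            for i in range(rng.randint(1, 15))]
    regions = [region(s, s + 100, uid=f"u{k}") for k, s in enumerate((50, 300, 700))]
    total = len(alns)

    def summarize(alignments, total_reads):
        track = qt.genome_coverage(alignments, {"chr1": 1000})
        loci = []
        for r in regions:
            mean = qt.mean_coverage(track, r)
            loci.append(qt.LocusExpression(r, 0, mean, qt.normalize(mean, total_reads)))
        return loci

    base = summarize(alns, total)
    doubled = summarize(alns + alns, 2 * total)
    for b, d in zip(base, doubled):
        assert d.mean_cov == pytest.approx(2 * b.mean_cov)
        assert d.normalized == pytest.approx(b.normalized)
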