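"""Reference pruning, LINE library construction and subfamily annotation."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from l1xpress.intervals import GenomicInterval, L1Region
from l1xpress import reference_prep as rp
from l1xpress.simulate import toy_l1_reference


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


class TestLoadBed:
    def test_bed6_fields(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tUID-1\t0\t+\n")
        (out,) = rp.load_bed(p)
        assert (out.chrom, out.start, out.end, out.name, out.strand) == (
            "chr1", 100, 200, "UID-1", "+")

    def test_bed3_defaults(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t5\t10\n")
        (out,) = rp.load_bed(p)
        assert out.name == "" and out.strand == "."

    @pytest.mark.parametrize("line", ["chr1\t200\t100", "chr1\tx\t100", "chr1\t100"])
    def test_malformed_line_names_lineno(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\n" + line + "\n")
        with pytest.raises(rp.BedParseError, match=":2"):
            rp.load_bed(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert rp.load_bed(p) == []

    def test_order_preserved(self, tmp_path):
        p = tmp_path / "o.bed"
        p.write_text("chr2\t10\t20\nchr1\t5\t9\n")
        out = rp.load_bed(p)
        assert [o.chrom for o in out] == ["chr2", "chr1"]


class TestSubtractOverlapping:
    def test_one_base_overlap_removes(self):
        assert rp.subtract_overlapping([iv("A", 0, 100)], [iv("A", 99, 150)]) == []

    def test_half_open_abutment_is_not_overlap(self):
        kept = rp.subtract_overlapping([iv("A", 0, 100)], [iv("A", 100, 150)])
        assert kept == [iv("A", 0, 100)]

    def test_per_chromosome_independence(self):
        kept = rp.subtract_overlapping(
            [iv("A", 0, 10), iv("B", 0, 10)], [iv("A", 5, 6)])
        assert kept == [iv("B", 0, 10)]

    def test_empty_blocking_is_identity(self):
        primary = [iv("A", 0, 10), iv("B", 3, 8)]
        assert rp.subtract_overlapping(primary, []) == primary

    def test_self_subtraction_is_empty(self):
        primary = [iv("A", 0, 10), iv("B", 3, 8)]
        assert rp.subtract_overlapping(primary, primary) == []


@st.composite
def interval_lists(draw):
    n = draw(st.integers(0, 12))
    out = []
    for _ in range(n):
        chrom = draw(st.sampled_from(["c1", "c2"]))
        start = draw(st.integers(0, 300))
        length = draw(st.integers(1, 60))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


@settings(max_examples=150, deadline=None)
@given(primary=interval_lists(), blocking=interval_lists())
def test_subtract_matches_all_pairs_bruteforce(primary, blocking):
    """Interval-tree subtraction equals the O(n*m) all-pairs overlap check."""
    expected = [
        p for p in primary if not any(p.overlaps(b) for b in blocking)
    ]
    assert rp.subtract_overlapping(primary, blocking) == expected


class TestExonExclusion:
    def test_one_bp_overlap_excluded(self):
        region = L1Region(iv("chr2", 1000, 7000), "active", "u1")
        assert rp.exclude_exon_overlaps([region], [iv("chr2", 6999, 7200)]) == []

    def test_strand_blind(self):
        region = L1Region(iv("chr2", 1000, 7000, strand="-"), "active", "u1")
        exon = iv("chr2", 2000, 2100, strand="+")
        assert rp.exclude_exon_overlaps([region], [exon]) == []

    def test_no_exons_is_identity(self):
        regions = [L1Region(iv("chr1", 0, 10), "orf2", "u")]
        assert rp.exclude_exon_overlaps(regions, []) == regions

    def test_categories_unchanged(self):
        regions = [
            L1Region(iv("chr1", 0, 10), "active", "a"),
            L1Region(iv("chr1", 20, 30), "inactive", "b"),
        ]
        kept = rp.exclude_exon_overlaps(regions, [iv("chr1", 200, 300)])
        assert [r.category for r in kept] == ["active", "inactive"]


class TestToyReferencePruning:
    """Fixed 30-region replica of the category-reference pruning."""

    def test_survivor_sets(self):
        active, inactive, orf2, exons = toy_l1_reference()
        a, i, o = rp.prune_references(active, inactive, orf2, exons)
        assert [r.uid for r in a] == ["A1", "A4", "A5", "A7"]
        assert [r.uid for r in i] == [
            "I1", "I2", "I3", "I4", "I6", "I8", "I9", "I11", "I12", "I13", "I15"]
        assert [r.uid for r in o] == ["O1", "O3", "O5", "O6"]

    def test_inactive_overlapping_active_is_retained(self):
        # pruning is asymmetric: only the active reference loses overlaps
        active, inactive, orf2, exons = toy_l1_reference()
        _, i, _ = rp.prune_references(active, inactive, orf2, exons)
        assert "I1" in [r.uid for r in i]


class TestBuildLineLibrary:
    GENOME = {"chr1": "ACGT" * 3000}  # 12 kb

    def rows(self, span, rep_class="LINE", strand="+", name="L1X"):
        return [{"genoName": "chr1", "genoStart": 100, "genoEnd": 100 + span,
                 "strand": strand, "repName": name, "repClass": rep_class,
                 "repFamily": "L1"}]

    def test_span_threshold_is_strict(self):
        assert rp.build_line_library(self.rows(4500), {}, self.GENOME) == []
        out = rp.build_line_library(self.rows(4501), {}, self.GENOME)
        assert len(out) == 1 and out[0][2] == "genome_track"
        assert len(out[0][1]) == 4501

    def test_non_line_class_excluded(self):
        assert rp.build_line_library(self.rows(6000, rep_class="SINE"), {}, self.GENOME) == []

    def test_consensus_entries_included(self):
        out = rp.build_line_library([], {"L1HS": "acgtacgt"}, self.GENOME)
        assert out == [("L1HS", "ACGTACGT", "consensus")]

    def test_minus_strand_reverse_complement(self):
        genome = {"chr1": "A" * 5000 + "ACGTT" + "A" * 5000}
        rows = [{"genoName": "chr1", "genoStart": 0, "genoEnd": 10005,
                 "strand": "-", "repName": "L1X", "repClass": "LINE", "repFamily": "L1"}]
        (entry,) = rp.build_line_library(rows, {}, genome)
        assert entry[1] == "T" * 5000 + "AACGT" + "T" * 5000

    def test_missing_sequence_errors(self):
        rows = self.rows(5000)
        rows[0]["genoName"] = "chrMissing"
        with pytest.raises(KeyError):
            rp.build_line_library(rows, {}, self.GENOME)


class TestAnnotateSubfamily:
    def region(self, start=10000, end=16000):
        return L1Region(iv("chr1", start, end), "active", "u1")

    def row(self, start, end, name):
        return {"genoName": "chr1", "genoStart": start, "genoEnd": end,
                "strand": "+", "repName": name, "repClass": "LINE", "repFamily": "L1"}

    def test_largest_overlap_wins(self):
        rows = [self.row(10000, 16000, "L1HS"), self.row(15950, 21000, "L1PA2")]
        (out,) = rp.annotate_subfamily([self.region()], rows)
        assert out.subfamily == "L1HS"

    def test_no_overlap_leaves_unset(self):
        (out,) = rp.annotate_subfamily([self.region()], [self.row(40000, 46000, "L1HS")])
        assert out.subfamily is None

    def test_short_rows_do_not_compete(self):
        # a 4.5 kb row is not a subfamily donor even if it overlaps most
        rows = [self.row(10000, 14500, "L1PA9")]
        (out,) = rp.annotate_subfamily([self.region()], rows)
        assert out.subfamily is None

    def test_tie_breaks_lexicographically(self):
        rows = [self.row(10000, 15000, "L1PA2"), self.row(11000, 16000, "L1HS")]
        (out,) = rp.annotate_subfamily([self.region()], rows)
        assert out.subfamily == "L1HS"

    def test_matches_exhaustive_overlap_comparison(self):
        """Tree-based assignment equals brute-force max-overlap over all rows."""
        rng = random.Random(11)
        rows = [self.row(s := rng.randint(0, 50000), s + rng.randint(4501, 8000),
                         rng.choice(["L1HS", "L1PA2", "L1PA3"]))
                for _ in range(40)]
        regions = [L1Region(iv("chr1", s := rng.randint(0, 50000), s + 6000),
                            "active", f"u{k}") for k in range(25)]
        out = rp.annotate_subfamily(regions, rows)
        for region, got in zip(regions, out):
            best, best_key = None, None
            for row in rows:
                ov = max(0, min(region.end, row["genoEnd"]) - max(region.start, row["genoStart"]))
                if ov <= 0:
                    continue
                key = (-ov, row["repName"])
                if best_key is None or key < best_key:
                    best, best_key = row["repName"], key
            assert got.subfamily == best
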