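"""Read assignment, counting, masking and RPKM."""

import pytest

from ribosig.annotation import TranscriptModel
from ribosig.quant import (
    AlignedRead,
    AssignmentError,
    build_count_profiles,
    midpoint_position,
    psite_position,
    quantify,
    read_length_histogram,
    rpkm,
)


def tx(tid, gid, start, end, strand="+", chrom="chr1", cds=0):
    return TranscriptModel(tid, gid, chrom, strand, ((start, end),), cds)


class TestPositionAssignment:
    def test_psite_plus_strand(self):
        assert psite_position(AlignedRead("c", 1000, 32, "+")) == 1012

    def test_psite_minus_strand(self):
        # 5' end of a minus-strand read is its rightmost base
        assert psite_position(AlignedRead("c", 1000, 32, "-")) == 1019

    def test_psite_offset_table_and_error(self):
        r = AlignedRead("c", 0, 30, "+")
        assert psite_position(r, {30: 11}) == 11
        with pytest.raises(AssignmentError):
            psite_position(AlignedRead("c", 0, 10, "+"))

    @pytest.mark.parametrize("length,start,expected", [(31, 100, 115), (32, 100, 115), (1, 7, 7)])
    def test_midpoint_plus(self, length, start, expected):
        assert midpoint_position(AlignedRead("c", start, length, "+")) == expected

    def test_midpoint_minus_mirrors_five_prime(self):
        # length 32 read at 100..131: 5' end 131, midpoint 131-15 = 116
        assert midpoint_position(AlignedRead("c", 100, 32, "-")) == 116


class TestCounting:
    def test_unique_reads_counted(self):
        t = tx("t1", "g1", 0, 2000)
        reads = [AlignedRead("chr1", 100 + i * 50, 32, "+") for i in range(5)]
        profiles, stats = build_count_profiles(reads, [t], "rf")
        assert profiles["t1"].total == 5
        assert stats["counted"] == 5

    def test_multimapped_reads_dropped(self):
        t = tx("t1", "g1", 0, 2000)
        profiles, stats = build_count_profiles(
            [AlignedRead("chr1", 100, 32, "+", n_alignments=3)], [t], "rf")
        assert profiles["t1"].total == 0
        assert stats["dropped_nonunique"] == 1

    def test_overlap_positions_masked_for_both_genes(self):
        a = tx("ta", "ga", 0, 500)
        b = tx("tb", "gb", 400, 900)  # 100-nt overlap at 400..500
        read_in_overlap = AlignedRead("chr1", 438, 32, "+")  # P-site 450
        profiles, stats = build_count_profiles([read_in_overlap], [a, b], "rf")
        assert profiles["ta"].total == 0 and profiles["tb"].total == 0
        assert stats["masked"] == 1
        assert profiles["ta"].excluded_mask[400:500].all()
        assert profiles["ta"].effective_length == 400

    def test_unknown_chromosome_skipped(self):
        t = tx("t1", "g1", 0, 500)
        _, stats = build_count_profiles(
            [AlignedRead("chrX", 100, 32, "+")], [t], "rf")
        assert stats["skipped_unknown_chrom"] == 1

    def test_read_conservation(self, rng):
        a = tx("ta", "ga", 0, 500)
        b = tx("tb", "gb", 450, 900)
        reads = [AlignedRead("chr1", int(s), 32, "+", int(n))
                 for s, n in zip(rng.integers(0, 1000, 300),
                                 rng.choice([1, 1, 1, 3], 300))]
        profiles, stats = build_count_profiles(reads, [a, b], "mrna")
        counted = sum(p.total for p in profiles.values())
        assert counted == stats["counted"]
        assert (stats["counted"] + stats["dropped_nonunique"] + stats["masked"]
                + stats["skipped_unknown_chrom"] + stats["outside_transcripts"]
                == stats["n_input"] == 300)

    def test_strand_symmetry(self):
        """Mirroring the layout to the minus strand leaves counts unchanged."""
        plus = tx("t1", "g1", 100, 600, "+")
        reads_plus = [AlignedRead("chr1", 150 + 40 * i, 32, "+") for i in range(8)]
        # mirror around genome length 700: position p -> 700 - (p + len)
        minus = tx("t1", "g1", 100, 600, "-")
        reads_minus = [AlignedRead("chr1", 700 - (r.start + r.length), r.length, "-")
                       for r in reads_plus]
        for mode in ("rf", "mrna"):
            p1, _ = build_count_profiles(reads_plus, [plus], mode)
            p2, _ = build_count_profiles(reads_minus, [minus], mode)
            assert p1["t1"].total == p2["t1"].total
            # the per-position profile is mirrored exactly
            assert (p1["t1"].counts == p2["t1"].counts).all()


class TestRpkm:
    @pytest.mark.parametrize("count,length,total,expected", [
        (10, 1000, 10 ** 6, 10.0), (50, 2500, 2 * 10 ** 7, 1.0), (0, 500, 10 ** 6, 0.0)])
    def test_values(self, count, length, total, expected):
        assert rpkm(count, length, total) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 10 ** 6)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)

    def test_invariant_under_duplication(self):
        assert rpkm(20, 1500, 2 * 10 ** 6) == pytest.approx(rpkm(10, 1500, 10 ** 6))

    def test_quantify_table(self):
        t1, t2 = tx("t1", "g1", 0, 1000), tx("t2", "g2", 2000, 3000)
        rf_reads = [AlignedRead("chr1", 100, 32, "+")] * 6
        mr_reads = [AlignedRead("chr1", 2100, 50, "+")] * 4
        rf, _ = build_count_profiles(rf_reads, [t1, t2], "rf")
        mr, _ = build_count_profiles(mr_reads, [t1, t2], "mrna")
        table = quantify(rf, mr, [t1, t2])
        assert table.loc["g1", "rf_count"] == 6
        assert table.loc["g2", "mrna_count"] == 4
        assert (table["rf_rpkm"] == 0).equals(table["rf_count"] == 0)


class TestReadLengthHistogram:
    def test_exact_histogram_and_mean(self):
        reads = [AlignedRead("c", 0, ln, "+") for ln in (30, 32, 34)]
        hist, mean = read_length_histogram(reads)
        assert hist == {30: 1, 32: 1, 34: 1}
        assert mean == pytest.approx(32.0)

    def test_uniform_lengths(self):
        reads = [AlignedRead("c", 0, 32, "+")] * 10
        _, mean = read_length_histogram(reads)
        assert mean == 32.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            read_length_histogram([])


class TestExports:
    def test_blacklisted_reads_discarded_and_conserved(self):
        t = tx("t1", "g1", 0, 500)
        reads = [AlignedRead("chr1", 100, 32, "+"),
                 AlignedRead("rRNA", 100, 32, "+")]
        profiles, stats = build_count_profiles(reads, [t], "rf",
                                               blacklist_chroms={"rRNA"})
        assert profiles["t1"].total == 1
        assert stats["blacklisted"] == 1
        assert stats["counted"] + stats["blacklisted"] == stats["n_input"]

    def test_bedgraph_merges_runs(self, tmp_path):
        from ribosig.quant import write_bedgraph

        t = tx("t1", "g1", 0, 100)
        reads = [AlignedRead("chr1", 10, 31, "+")] * 3 + [AlignedRead("chr1", 11, 31, "+")] * 3
        profiles, _ = build_count_profiles(reads, [t], "mrna")
        out = tmp_path / "x.bedGraph"
        write_bedgraph(profiles, [t], out)
        # midpoints 25 and 26, both count 3: one merged interval
        assert out.read_text() == "chr1\t25\t27\t3\n"
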