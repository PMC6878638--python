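"""Jump classification, deduplication, summaries and span histograms."""

import numpy as np
import pytest

from fosjump import classify as cl


def end(read_id, side, contig, start, length, strand, mapq=60):
    return cl.AlignedEnd(read_id, side, contig, start, start + length, strand, mapq)


def pair_at(span, strands, contig="c1", read_id="r", end_len=2_000):
    """A pair with the requested outer span and (left, right) strands."""
    left = end(read_id, 1, contig, 10_000, end_len, strands[0])
    right = end(read_id, 2, contig, 10_000 + span - end_len, end_len, strands[1])
    return left, right


class TestClassifyPair:
    def test_decision_table_oracle(self):
        """Exhaustive orientation x spacing enumeration against an
        independently written decision table."""
        spans = {10_000: "short", 35_000: "window", 60_000: "long", 150_000: "verylong"}
        orientations = {
            ("+", "-"): "convergent",
            ("-", "+"): "divergent",
            ("+", "+"): "tandem",
            ("-", "-"): "tandem",
        }

        def oracle(orient, span_class):
            if orient != "convergent":
                return "chim_orientation"
            return {
                "short": "chim_short",
                "window": "correct",
                "long": "chim_long",
                "verylong": "chim_long",
            }[span_class]

        for span, span_class in spans.items():
            for strands, orient in orientations.items():
                left, right = pair_at(span, strands)
                j = cl.classify_pair(left, right)
                assert j.label == oracle(orient, span_class), (span, strands)
                assert j.orientation == orient
                assert j.span == span
                assert j.over_long_cut == (span > 100_000)

    def test_intercontig(self):
        j = cl.classify_pair(end("r", 1, "c1", 100, 2_000, "+"), end("r", 2, "c2", 100, 2_000, "-"))
        assert j.label == "chim_intercontig"
        assert j.span is None and j.orientation == "intercontig"

    def test_span_is_outermost_distance(self):
        j = cl.classify_pair(end("r", 1, "c1", 5_000, 3_000, "+"), end("r", 2, "c1", 40_000, 1_000, "-"))
        assert j.span == 41_000 - 5_000

    def test_unordered_input_is_canonicalised(self):
        l, r = pair_at(38_000, ("+", "-"))
        assert cl.classify_pair(r, l).label == "correct"


class TestLoadAlignments:
    @pytest.fixture()
    def fixture_alignments(self, tmp_path):
        """The same three alignments as SAM (via pysam) and as PAF text."""
        import pysam

        rows = [
            ("r1/1", "c1", 100, 2_000, "+", 60),
            ("r1/2", "c1", 37_000, 1_500, "-", 60),
            ("r2/1", "c2", 500, 1_000, "+", 0),
        ]
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c1", "LN": 100_000}, {"SN": "c2", "LN": 50_000}]}
        sam = tmp_path / "ends.sam"
        with pysam.AlignmentFile(str(sam), "wh", header=header) as fh:
            for name, contig, start, length, strand, mapq in rows:
                a = pysam.AlignedSegment(fh.header)
                a.query_name = name
                a.query_sequence = "A" * length
                a.reference_name = contig
                a.reference_start = start
                a.cigarstring = f"{length}M"
                a.mapping_quality = mapq
                a.flag = 16 if strand == "-" else 0
                fh.write(a)
        paf = tmp_path / "ends.paf"
        with open(paf, "w") as fh:
            for name, contig, start, length, strand, mapq in rows:
                fh.write(
                    "\t".join(
                        map(
                            str,
                            [name, length, 0, length, strand, contig, 100_000, start, start + length, length, length, mapq],
                        )
                    )
                    + "\n"
                )
        return str(sam), str(paf)

    def test_sam_and_paf_agree(self, fixture_alignments):
        sam, paf = fixture_alignments
        from_sam = cl.load_alignments(sam)
        from_paf = cl.load_alignments(paf)
        assert set(from_sam) == set(from_paf) == {("r1", 1), ("r1", 2), ("r2", 1)}
        for key in from_sam:
            a, b = from_sam[key], from_paf[key]
            assert (a.contig, a.start, a.end, a.strand, a.mapq) == (b.contig, b.start, b.end, b.strand, b.mapq)

    def test_mapq_zero_counts_as_ambiguous(self, fixture_alignments):
        ends = cl.load_alignments(fixture_alignments[0])
        jumps, ambiguous = cl.pair_and_classify(ends)
        assert len(jumps) == 1 and jumps[0].read_id == "r1"
        assert ambiguous == 1  # r2 has one mapq-0 end and no partner

    def test_missing_side_suffix_rejected(self, tmp_path):
        paf = tmp_path / "bad.paf"
        paf.write_text("read1\t100\t0\t100\t+\tc1\t1000\t0\t100\t100\t100\t60\n")
        with pytest.raises(ValueError, match="suffix"):
            cl.load_alignments(str(paf))


class TestDeduplicate:
    def test_identical_start_sites_collapse(self):
        j1 = cl.classify_pair(*pair_at(38_000, ("+", "-"), read_id="a"))
        j2 = cl.classify_pair(*pair_at(38_000, ("+", "-"), read_id="b"))
        unique, ndup = cl.deduplicate([j1, j2])
        assert len(unique) == 1 and ndup == 1
        assert unique[0].read_id == "a"  # first in read-id order represents

    def test_one_bp_jitter_keeps_both(self):
        j1 = cl.classify_pair(*pair_at(38_000, ("+", "-"), read_id="a"))
        l, r = pair_at(38_000, ("+", "-"), read_id="b")
        l2 = cl.AlignedEnd(l.read_id, l.side, l.contig, l.start + 1, l.end + 1, l.strand, l.mapq)
        j2 = cl.classify_pair(l2, r)
        unique, ndup = cl.deduplicate([j1, j2])
        assert len(unique) == 2 and ndup == 0

    def test_idempotent(self):
        rng = np.random.default_rng(51)
        jumps = []
        for i in range(100):
            start = int(rng.integers(0, 10))  # heavy collisions
            l = end(f"r{i}", 1, "c1", 10_000 + start, 2_000, "+")
            r = end(f"r{i}", 2, "c1", 45_000 + start, 2_000, "-")
            jumps.append(cl.classify_pair(l, r))
        u1, d1 = cl.deduplicate(jumps)
        u2, d2 = cl.deduplicate(u1)
        assert [j.read_id for j in u1] == [j.read_id for j in u2] and d2 == 0

    def test_matches_bruteforce_grouping_oracle(self):
        rng = np.random.default_rng(52)
        jumps = []
        keys = []
        for i in range(300):
            s1 = int(rng.integers(0, 20))
            s2 = int(rng.integers(0, 20))
            l = end(f"r{i:03d}", 1, "c1", 10_000 + s1, 2_000, "+")
            r = end(f"r{i:03d}", 2, "c1", 45_000 + s2, 2_000, "-")
            jumps.append(cl.classify_pair(l, r))
            keys.append((l.start, r.end))  # 5' sites of + and - reads
        unique, ndup = cl.deduplicate(jumps)
        assert len(unique) == len(set(keys))
        assert ndup == len(jumps) - len(set(keys))


class TestSummary:
    def test_chimaera_rate_arithmetic(self):
        jumps = [cl.classify_pair(*pair_at(38_000, ("+", "-"), read_id=f"ok{i}")) for i in range(95)]
        jumps += [cl.classify_pair(*pair_at(10_000, ("+", "-"), read_id=f"bad{i}")) for i in range(5)]
        s = cl.summarize(jumps)
        assert s.n_unique == 100
        assert s.chimaera_rate == pytest.approx(0.05)
        assert s.correct_fraction == pytest.approx(0.95)

    def test_methods_convention_ignores_moderate_spacing(self):
        jumps = [cl.classify_pair(*pair_at(38_000, ("+", "-"), read_id=f"ok{i}")) for i in range(8)]
        jumps.append(cl.classify_pair(*pair_at(60_000, ("+", "-"), read_id="mid")))  # 50k<span<100k
        jumps.append(cl.classify_pair(*pair_at(150_000, ("+", "-"), read_id="far")))
        s = cl.summarize(jumps, convention="methods")
        assert s.chimaera_rate == pytest.approx(1 / 10)
        s2 = cl.summarize(jumps, convention="results")
        assert s2.chimaera_rate == pytest.approx(2 / 10)

    def test_category_counts_partition_unique_pairs(self):
        rng = np.random.default_rng(53)
        jumps = []
        for i in range(200):
            span = int(rng.integers(1_000, 200_000))
            strands = [("+", "-"), ("-", "+"), ("+", "+")][int(rng.integers(0, 3))]
            jumps.append(cl.classify_pair(*pair_at(span, strands, read_id=f"r{i}")))
        cl.deduplicate(jumps)
        s = cl.summarize(jumps)
        assert sum(s.counts.values()) == s.n_unique

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cl.summarize([])


class TestSpanHistogram:
    def test_single_bin_at_hundred_percent(self):
        jumps = [cl.classify_pair(*pair_at(38_500, ("+", "-"), read_id=f"r{i}", end_len=1_000)) for i in range(5)]
        for i, j in enumerate(jumps):  # de-collide start sites
            jumps[i] = cl.classify_pair(
                end(j.read_id, 1, "c1", 10_000 + i, 1_000, "+"),
                end(j.read_id, 2, "c1", 10_000 + i + 36_500, 2_000, "-"),
            )
        h = cl.span_histogram(jumps)
        assert len(h) == 1
        assert h.iloc[0]["bin_start"] == 38_000
        assert h.iloc[0]["percent"] == pytest.approx(100.0)

    def test_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(54)
        jumps = []
        for i in range(150):
            span = int(rng.integers(20_000, 50_000))
            jumps.append(cl.classify_pair(*pair_at(span, ("+", "-"), read_id=f"r{i}")))
        h = cl.span_histogram(jumps)
        assert h["percent"].sum() == pytest.approx(100.0)

    def test_table_round_trip(self):
        jumps = [cl.classify_pair(*pair_at(38_000, ("+", "-"), read_id=f"r{i}")) for i in range(10)]
        cl.deduplicate(jumps)
        back = cl.jumps_from_table(cl.jumps_table(jumps))
        assert [(j.read_id, j.label, j.span, j.duplicate) for j in back] == [
            (j.read_id, j.label, j.span, j.duplicate) for j in jumps
        ]
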