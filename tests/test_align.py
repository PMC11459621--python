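import random

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from gpseq.align import (
    AnchorAligner,
    Placement,
    ScoringScheme,
    Unplaced,
    import_anchor_sam,
    position_r1,
    revcomp,
    sw_local,
    trim_paired,
)
from gpseq.io import ReadPair, ReferenceSet, write_sam
from gpseq.preprocess import BoundaryAnnotation, PipelineParams

from conftest import make_paired, make_placement
from _oracles import sw_score_oracle

P = PipelineParams()


class TestSmithWaterman:
    def test_identical_ten_mers(self):
        assert sw_local("ACGTACGTAC", "ACGTACGTAC").score == 50

    def test_free_mismatch_beats_gap(self):
        # 7 ungapped matches (35) beat the 8-match/1-deletion path (34)
        # because mismatches cost nothing under the GPS scheme
        aln = sw_local("AAAATTTT", "AAAAGTTTT")
        assert aln.score == 35 == sw_score_oracle("AAAATTTT", "AAAAGTTTT")

    def test_ct_wildcard_is_asymmetric(self):
        ct = ScoringScheme(bisulfite_mode="CT")
        assert sw_local("TTTT", "TCTC", ct).score == 20  # read T matches ref C
        assert sw_local("CCCC", "TTTT", ct).score == 0  # ref T never matches read C

    def test_ga_wildcard(self):
        ga = ScoringScheme(bisulfite_mode="GA")
        assert sw_local("AAAA", "GAGA", ga).score == 20
        assert sw_local("GGGG", "AAAA", ga).score == 0

    def test_single_substitution(self):
        assert sw_local("ACGTACGTAC", "ACGTTCGTAC").score == 45

    def test_empty_or_hopeless_input(self):
        assert sw_local("", "ACGT").score == 0
        assert sw_local("AAAA", "").score == 0
        aln = sw_local("A", "T")
        assert aln.score == 0 and aln.cigar == []

    def test_n_never_matches(self):
        assert sw_local("NNNN", "NNNN").score == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_random_pairs_equal_oracle(self, seed):
        rnd = random.Random(seed)
        for _ in range(60):
            mode = rnd.choice(["off", "CT", "GA"])
            q = "".join(rnd.choice("ACGTN") for _ in range(rnd.randint(1, 60)))
            t = "".join(rnd.choice("ACGTN") for _ in range(rnd.randint(1, 60)))
            aln = sw_local(q, t, ScoringScheme(bisulfite_mode=mode))
            assert aln.score == sw_score_oracle(q, t, mode)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=30),
        st.text(alphabet="ACGT", min_size=1, max_size=30),
        st.text(alphabet="ACGT", max_size=8),
        st.text(alphabet="ACGT", max_size=8),
    )
    def test_appending_never_decreases_score(self, q, t, q_extra, t_extra):
        base = sw_local(q, t).score
        assert sw_local(q + q_extra, t + t_extra).score >= base

    def test_cigar_is_consistent_with_offsets(self):
        aln = sw_local("ACGTACGTAC", "ACGTTTACGTAC")
        q_span = sum(ln for op, ln in aln.cigar if op in "MI")
        t_span = sum(ln for op, ln in aln.cigar if op in "MD")
        assert q_span == aln.q_end - aln.q_start
        assert t_span == aln.t_end - aln.t_start


def _random_ref(n, seed=0, name="chr1"):
    rnd = random.Random(seed)
    return ReferenceSet({name: "".join(rnd.choice("ACGT") for _ in range(n))})


class TestAnchorAligner:
    def test_unique_anchor_found_at_true_position(self):
        ref = _random_ref(5000, seed=1)
        anchor = ref["chr1"][1234:1284]
        hits = AnchorAligner(ref).align(anchor, P)
        assert len(hits) == 1
        assert (hits[0].start0, hits[0].strand) == (1234, "+")
        assert hits[0].score == 250 and hits[0].n_candidates == 1

    def test_reverse_strand_anchor(self):
        ref = _random_ref(5000, seed=2)
        anchor = revcomp(ref["chr1"][800:850])
        hits = AnchorAligner(ref).align(anchor, P)
        assert hits and (hits[0].start0, hits[0].strand) == (800, "-")

    def test_repeat_array_capped_at_max_hits(self):
        rnd = random.Random(3)
        unit = "".join(rnd.choice("ACGT") for _ in range(40))
        spacers = [
            "".join(rnd.choice("ACGT") for _ in range(60)) for _ in range(25)
        ]
        ref = ReferenceSet({"chr1": "".join(u + s for u, s in zip([unit] * 25, spacers))})
        hits = AnchorAligner(ref).align(unit, P)
        assert 1 <= len(hits) <= 20

    def test_absent_anchor_returns_empty(self):
        ref = ReferenceSet({"chr1": "AT" * 3000})
        assert AnchorAligner(ref).align("GCGCGTTACGGATCGATCGGCTTAGCCGATA", P) == []


class TestPositionR1:
    def test_short_random_r1_unplaced(self):
        """A query too short to reach the score floor is rejected.  (Because
        mismatches cost nothing, any full-length random read collects enough
        chance matches in a 1 kb window to pass min_sw_score; the floor only
        filters short or heavily clipped queries.)"""
        ref = _random_ref(4000, seed=4)
        anchor_hit = AnchorAligner(ref).align(ref["chr1"][2000:2050], P)
        rnd = random.Random(5)
        junk = "".join(rnd.choice("ACGT") for _ in range(12))  # max score 60 < 100
        result = position_r1("x", junk, anchor_hit, ref, P)
        assert isinstance(result, Unplaced) and result.reason == "low_score"

    def test_placed_on_simulation_truth(self, small_run):
        prov = small_run["truth"].provenance.set_index("id")
        placed = small_run["placed"]
        assert len(placed) > 800
        correct = sum(
            1
            for pp in placed
            if pp.r1_placement.start0 == prov.loc[pp.pair_id, "r1_true_start"]
        )
        assert correct / len(placed) >= 0.99
        assert all(pp.pair_distance <= P.max_pair_distance for pp in placed)
        # R1/R2 inward-facing on opposite strands
        assert all(
            {pp.r1_placement.strand, pp.r2_placement.strand} == {"+", "-"}
            for pp in placed
        )


class TestTrim:
    def _pp(self, ref_seq, r1_query, strand="+", start0=0):
        ref = ReferenceSet({"chr1": ref_seq})
        r1 = make_placement("chr1", start0, strand, r1_query)
        r2 = make_placement("chr1", start0, "-" if strand == "+" else "+", "G" * 40)
        pp = make_paired("t", r1, r2)
        ann = BoundaryAnnotation(38, "G" * 38)
        return trim_paired(pp, ref, ann, P), ref

    def test_r2_keep_is_boundary(self):
        ref_seq = "A" * 60
        pp, _ = self._pp(ref_seq, "A" * 60)
        assert pp.r2_keep == 38

    def test_first_conversion_sets_keep(self):
        # ref C at positions 10 and 40; read retains C at 40 (patched),
        # converted T at 10 -> keep-span ends just past position 10
        ref_seq = ("A" * 10 + "C" + "A" * 29 + "C" + "A" * 19)
        read = "A" * 10 + "T" + "A" * 29 + "C" + "A" * 19
        pp, _ = self._pp(ref_seq, read)
        assert pp.r1_keep == 11

    def test_fully_converted_keeps_whole_read(self):
        ref_seq = "A" * 59 + "C"
        read = "A" * 59 + "T"  # terminal base is the first conversion
        pp, _ = self._pp(ref_seq, read)
        assert pp.r1_keep == 60

    def test_no_reference_c_keeps_whole_read(self):
        pp, _ = self._pp("ATAT" * 15, "ATAT" * 15)
        assert pp.r1_keep == 60

    def test_no_conversion_drops_whole_read(self):
        ref_seq = "A" * 10 + "C" + "A" * 49
        read = "A" * 10 + "C" + "A" * 49  # cytosine retained everywhere
        pp, _ = self._pp(ref_seq, read)
        assert pp.r1_keep == 0

    def test_minus_strand_scan_direction(self):
        # minus placement: stored query is revcomp(R1); R1's 3' end is the
        # SMALLEST stored coordinate.  Ref G at stored coord 5 read as A is
        # the first conversion from R1's 3' end -> keep = L - 5
        ref_seq = "T" * 5 + "G" + "T" * 54
        query = "T" * 5 + "A" + "T" * 54
        ref = ReferenceSet({"chr1": ref_seq})
        r1 = make_placement("chr1", 0, "-", query)
        r2 = make_placement("chr1", 300, "+", "G" * 40)
        pp = make_paired("t", r1, r2)
        pp = trim_paired(pp, ref, BoundaryAnnotation(40, "G" * 40), P)
        assert pp.r1_keep == 60 - 5


class TestSamRoundTrip:
    def test_cigar_and_columns_roundtrip(self, tmp_path):
        ref = ReferenceSet({"chr1": "ACGTACGTAC" + "TT" + "GGATCCGGAT" + "A" * 40})
        # engineered gapped alignment
        query = "ACGTACGTACGGATCCGGAT"  # skips the TT insert in the reference
        aln = sw_local(query, ref["chr1"])
        assert any(op == "D" for op, _ in aln.cigar)
        r1 = Placement("chr1", aln.t_start, "+", aln.score, aln.cigar, aln.q_start, aln.q_end, query)
        r2 = make_placement("chr1", 30, "-", "A" * 20)
        pp = make_paired("rt", r1, r2)
        pp.pair = ReadPair("rt", query, "T" * 20, "I" * len(query), "I" * 20)
        path = tmp_path / "rt.sam"
        write_sam([pp], ref, path)
        with pysam.AlignmentFile(str(path)) as fh:
            seg = next(iter(fh))
        got = [(q, t) for q, t in seg.get_aligned_pairs() if q is not None and t is not None]
        expect = list(r1.aligned_columns())
        assert got == expect

    def test_import_anchor_sam_roundtrip(self, tmp_path):
        ref = _random_ref(2000, seed=9)
        anchor = ref["chr1"][500:550]
        hits = AnchorAligner(ref).align(anchor, P)
        pp = make_paired("imp", hits[0], make_placement("chr1", 700, "-", "A" * 20))
        pp.pair = ReadPair("imp", anchor, "T" * 20, "I" * 50, "I" * 20)
        path = tmp_path / "anchors.sam"
        write_sam([pp], ref, path)
        imported = import_anchor_sam(path, ref)
        assert "imp" in imported
        got = imported["imp"][0]
        assert (got.contig, got.start0, got.strand) == ("chr1", 500, "+")
        assert got.score == hits[0].score

    def test_import_unknown_contig_raises(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:other\tLN:1000\n"
            "r1\t0\tother\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\n"
        )
        with pytest.raises(KeyError):
            import_anchor_sam(path, ReferenceSet({"chr1": "ACGT" * 100}))
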