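import random

import pytest
from hypothesis import given, settings, strategies as st

from gpseq.io import ReadPair
from gpseq.preprocess import (
    PipelineParams,
    deduplicate,
    detect_r2_boundary,
    estimate_incorporation_length,
    quality_filter,
)
from gpseq.simulate import SimConfig, simulate_library

from _oracles import boundary_oracle

P = PipelineParams()


def _pair(q1_frac_good: float, n: int = 150) -> ReadPair:
    good = int(round(q1_frac_good * n))
    qual = chr(33 + 40) * good + chr(33 + 20) * (n - good)
    return ReadPair("x", "A" * n, "A" * n, qual, qual)


class TestQualityFilter:
    def test_80pct_qualified_kept(self):
        assert quality_filter(_pair(0.8), P) == (True, None)

    def test_60pct_qualified_dropped(self):
        keep, reason = quality_filter(_pair(0.6), P)
        assert not keep and reason == "low_quality"

    def test_exact_threshold_kept(self):
        assert quality_filter(_pair(0.70), P)[0]

    def test_one_bad_mate_drops_pair(self):
        good = chr(33 + 40) * 150
        bad = chr(33 + 20) * 150
        assert not quality_filter(ReadPair("x", "A" * 150, "A" * 150, good, bad), P)[0]

    def test_empty_read_dropped(self):
        assert quality_filter(ReadPair("x", "", "A", "", "I"), P) == (False, "empty_read")


class TestDeduplicate:
    def test_exact_duplicate_removed(self):
        a = ReadPair("a", "ACGT", "TTTT", "IIII", "IIII")
        b = ReadPair("b", "ACGT", "TTTT", "JJJJ", "JJJJ")  # same seqs, diff quals
        assert [p.id for p in deduplicate([a, b])] == ["a"]

    def test_one_base_difference_kept(self):
        a = ReadPair("a", "ACGT", "TTTT", "IIII", "IIII")
        b = ReadPair("b", "ACGT", "TTTA", "IIII", "IIII")
        assert len(list(deduplicate([a, b]))) == 2

    def test_idempotent_and_order_preserving(self):
        rnd = random.Random(0)
        pairs = [
            ReadPair(str(i), rnd.choice(["AA", "CC", "GG"]), rnd.choice(["TT", "AA"]), "II", "II")
            for i in range(50)
        ]
        once = list(deduplicate(pairs))
        twice = list(deduplicate(once))
        assert once == twice
        ids = [p.id for p in once]
        assert ids == sorted(ids, key=lambda i: int(i))
        assert {(p.r1_seq, p.r2_seq) for p in pairs} == {(p.r1_seq, p.r2_seq) for p in once}


class TestBoundary:
    def test_minimal_kept_anchor(self):
        ann = detect_r2_boundary("A" * 33 + "TG" + "TTTTT", P)
        assert ann.r2_boundary == 35 and not ann.discarded
        assert ann.anchor_seq == "A" * 33 + "TG"

    def test_short_anchor_discarded(self):
        ann = detect_r2_boundary("TG" + "A" * 20, P)
        assert ann.discarded and ann.reason == "too_short" and ann.r2_boundary == 2

    def test_no_candidate_discarded(self):
        ann = detect_r2_boundary("CGCGCGCG", P)
        assert ann.discarded and ann.reason == "no_boundary"

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=200))
    def test_matches_exhaustive_oracle(self, seq):
        ann = detect_r2_boundary(seq, P)
        expect = boundary_oracle(seq)
        assert ann.r2_boundary == expect
        if expect is not None:
            # anchor is a literal prefix; suffix free of [ATG]G dinucleotides
            assert ann.anchor_seq == seq[: ann.r2_boundary or 0]
            suffix = seq[expect:]
            for d in ("AG", "TG", "GG"):
                assert d not in suffix
            assert ann.discarded == (expect < P.min_anchor_len)

    def test_boundary_never_exceeds_patch_on_clean_simulation(self):
        """With perfect conversion and CpG-only methylation, patch evidence
        cannot occur beyond the true patch, and within it the boundary is
        the last non-CpG G."""
        cfg = SimConfig(
            genome_length=20_000,
            n_pairs=200,
            conversion_rate=1.0,
            meth_protection_failure=0.0,
            seq_error_rate=0.0,
            duplicate_fraction=0.0,
            seed=8,
        )
        _, _, truth, pairs = simulate_library(cfg)
        prov = truth.provenance.set_index("id")
        checked = 0
        for p in pairs:
            patch = int(prov.loc[p.id, "frag_patch"])
            ann = detect_r2_boundary(p.r2_seq, P)
            if ann.r2_boundary is None:
                continue
            assert ann.r2_boundary <= patch
            assert ann.r2_boundary == boundary_oracle(p.r2_seq[:patch])
            checked += 1
        assert checked > 150


class TestIncorporationLength:
    FWD = "AATGATACGGCGACCACCGAGA"
    IDX = "CAAGCAGAAGACGGCATACGAG"

    @staticmethod
    def _rc(s):
        return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]

    def _clone_a(self, insert):
        return self.FWD + insert + self._rc(self.IDX)

    def _clone_b(self, insert):
        return self.IDX + insert + self._rc(self.FWD)

    def test_orientation_a_patch_extent(self):
        # non-CpG Cs only within the final 40 nt; farthest is 40 from the 3' end
        insert = "TATT" * 20 + "CA" + "TA" * 19
        est = estimate_incorporation_length(self._clone_a(insert), self.FWD, self.IDX)
        assert est.orientation == "A" and est.length == 40

    def test_orientation_b_last_noncpg_g(self):
        insert = "TA" * 10 + "GA" + "TTAA" * 10
        est = estimate_incorporation_length(self._clone_b(insert), self.FWD, self.IDX)
        assert est.orientation == "B" and est.length == 21

    def test_fully_converted_insert_length_zero(self):
        est = estimate_incorporation_length(self._clone_a("TATTATTA" * 10), self.FWD, self.IDX)
        assert est.length == 0

    def test_cpg_bases_are_not_patch_evidence(self):
        # every C is in CpG context: no evidence
        est = estimate_incorporation_length(self._clone_a("TACGTACGTACG" * 4), self.FWD, self.IDX)
        assert est.length == 0

    def test_reference_resolves_artifact(self):
        """A spurious distal G beyond conversion-proven positions is ignored
        once the reference shows intervening G->A conversions."""
        ref = "TTAGTTAGTTAG" + "TAGA" * 10 + "TTGTT"
        # patch = first 12 nt (Gs retained); beyond it all Gs converted to A,
        # except one artifact G near the 3' end
        read = "TTAGTTAGTTAG" + "TAAA" * 10 + "TTGTT"
        naive = estimate_incorporation_length(self._clone_b(read), self.FWD, self.IDX)
        assert naive.length > 12
        refined = estimate_incorporation_length(self._clone_b(read), self.FWD, self.IDX, ref=ref)
        assert refined.length == 12 and refined.resolved_by_ref

    def test_primer_not_found(self):
        with pytest.raises(ValueError, match="primer"):
            estimate_incorporation_length("TTTTTTTT", self.FWD, self.IDX)
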