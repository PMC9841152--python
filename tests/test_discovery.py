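import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrcall.alignment_io import AlignedRead
from lrcall.discovery import (
    DEL,
    INS,
    SNV,
    DepthProfile,
    ReadSupport,
    ReadVariant,
    aggregate_candidates,
    extract_read_variants,
    left_align_parsimonious,
    normalize_variant,
)
from oracles import leftmost_parsimonious, random_single_edit


def _read(seq, cigar, start=0, quals=None, **kw):
    return AlignedRead(
        "r1", "c", start, 60, cigar, seq, quals or [30] * len(seq), **kw
    )


class TestExtraction:
    def test_identity_alignment_yields_nothing(self):
        assert extract_read_variants(_read("ACGT", [(0, 4)]), "ACGT") == []

    def test_single_mismatch_in_match_span(self):
        vs = extract_read_variants(_read("AACTA", [(0, 5)]), "AACCA")
        assert [(v.pos, v.ref_allele, v.alt_allele, v.vtype) for v in vs] == [
            (3, "C", "T", SNV)
        ]

    def test_insertion_operator(self):
        vs = extract_read_variants(_read("ACGTT", [(0, 2), (1, 1), (0, 2)]), "ACTT")
        assert [(v.pos, v.ref_allele, v.alt_allele, v.vtype) for v in vs] == [
            (2, "", "G", INS)
        ]

    def test_deletion_operator(self):
        vs = extract_read_variants(_read("ACTT", [(0, 2), (2, 2), (0, 2)]), "ACGGTT")
        assert [(v.pos, v.ref_allele, v.alt_allele, v.vtype) for v in vs] == [
            (2, "GG", "", DEL)
        ]

    def test_equals_and_x_operators_treated_as_match(self):
        vs = extract_read_variants(_read("AACTA", [(7, 3), (8, 1), (7, 1)]), "AACCA")
        assert len(vs) == 1 and vs[0].pos == 3

    def test_soft_clips_consume_query_only(self):
        vs = extract_read_variants(_read("GGACGT", [(4, 2), (0, 4)], start=0), "ACGT")
        assert vs == []

    def test_n_bases_suppress_candidates(self):
        assert extract_read_variants(_read("ANGT", [(0, 4)]), "ACGT") == []
        assert extract_read_variants(_read("ACGT", [(0, 4)]), "ANGT") == []

    def test_adjacent_mismatches_are_independent_snvs(self):
        vs = extract_read_variants(_read("ATTA", [(0, 4)]), "ACCA")
        assert [(v.pos, v.alt_allele) for v in vs] == [(1, "T"), (2, "T")]
        assert all(v.support.var_count == 2 for v in vs)

    def test_terminal_insertion_is_not_a_candidate(self):
        vs = extract_read_variants(_read("GGACGT", [(1, 2), (0, 4)]), "ACGT")
        assert vs == []

    def test_support_metadata(self):
        quals = [10, 20, 30, 40, 50]
        vs = extract_read_variants(_read("AACTA", [(0, 5)], quals=quals), "AACCA")
        s = vs[0].support
        assert s.site_qual == 40
        assert s.window_qual == pytest.approx(np.mean(quals))
        assert s.rel_pos == pytest.approx(3 / 4)
        assert s.aligned_length == 5

    def test_window_quality_clipped_at_read_ends(self):
        # 11-position window would extend past both ends of a 5 bp read
        quals = [20, 25, 30, 35, 40]
        vs = extract_read_variants(_read("AATCA", [(0, 5)], quals=quals), "AACCA")
        assert vs[0].support.window_qual == pytest.approx(30.0)


class TestNormalization:
    def test_snv_is_fixed_point(self):
        assert normalize_variant(3, "C", "T", "AACCA") == (3, "C", "T")

    def test_deletion_shifts_to_leftmost_repeat(self):
        #       0123456
        ref = "GCACACA"
        # delete the rightmost "CA" (pos 5): leftmost equivalent is pos 1
        pos, r, a = normalize_variant(5, "CA", "", ref)
        assert (pos, r, a) == (1, "CA", "")
        assert leftmost_parsimonious(ref, "GCACA") == (1, "CA", "")

    def test_insertion_shifts_to_run_start(self):
        ref = "TAAAG"
        pos, r, a = normalize_variant(3, "", "AAA", ref)
        assert (pos, r, a) == (1, "", "AAA")
        assert leftmost_parsimonious(ref, "TAAAAAAG") == (1, "", "AAA")

    def test_shared_bases_are_trimmed(self):
        # "CAT" -> "CT" expressed redundantly
        assert normalize_variant(0, "CAT", "CT", "CATG") == (1, "A", "")

    def test_insertion_at_contig_start_anchors_at_zero(self):
        assert normalize_variant(1, "", "A", "AAAG") == (0, "", "A")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_extraction_plus_normalization_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        ref, alt_seq, _, _, _, cigar, read_seq = random_single_edit(rng)
        read = _read(read_seq, cigar)
        vs = extract_read_variants(read, ref)
        assert len(vs) == 1
        v = left_align_parsimonious(vs[0], ref)
        assert (v.pos, v.ref_allele, v.alt_allele) == leftmost_parsimonious(ref, alt_seq)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_normalization_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        ref, _, pos, ref_a, alt_a, _, _ = random_single_edit(rng)
        once = normalize_variant(pos, ref_a, alt_a, ref)
        assert normalize_variant(*once, ref) == once


class TestAggregation:
    @staticmethod
    def _support(reverse=False, var_count=1):
        return ReadSupport(reverse, 60, 30.0, 30.0, 0.5, 100, var_count)

    def _depth(self, value=10, length=50):
        d = DepthProfile("c", 0, length)
        d._depth[:] = value
        return d

    def test_identical_variants_merge_with_counts(self):
        vs = [ReadVariant("c", 5, "A", "G", SNV, self._support()) for _ in range(3)]
        cands = aggregate_candidates(vs, self._depth(10))
        assert len(cands) == 1
        assert cands[0].alt_count == 3 and cands[0].site_depth == 10

    def test_different_alts_stay_distinct(self):
        vs = [
            ReadVariant("c", 5, "A", "G", SNV, self._support()),
            ReadVariant("c", 5, "A", "T", SNV, self._support()),
        ]
        cands = aggregate_candidates(vs, self._depth())
        assert len(cands) == 2

    def test_empty_stream(self):
        assert aggregate_candidates([], self._depth()) == []

    def test_alt_count_conservation(self):
        rng = np.random.default_rng(0)
        vs = [
            ReadVariant("c", int(rng.integers(0, 10)), "A", "G", SNV, self._support())
            for _ in range(100)
        ]
        cands = aggregate_candidates(vs, self._depth(200))
        assert sum(c.alt_count for c in cands) == 100

    def test_deletion_depth_uses_span_minimum(self):
        d = DepthProfile("c", 0, 50)
        d._depth[:] = 30
        d._depth[12] = 7
        vs = [ReadVariant("c", 10, "AAAAA", "", DEL, self._support())]
        cands = aggregate_candidates(vs, d)
        assert cands[0].site_depth == 7

    def test_strands_seen_reflects_supporting_reads(self):
        vs = [
            ReadVariant("c", 5, "A", "G", SNV, self._support(reverse=False)),
            ReadVariant("c", 5, "A", "G", SNV, self._support(reverse=True)),
        ]
        cands = aggregate_candidates(vs, self._depth())
        assert cands[0].strands_seen == (True, True)
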