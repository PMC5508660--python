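"""End trimming, Hamming distance, mismatch enumeration, adapter stripping."""

from itertools import product
from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fastqprep.simulate import FixtureSpec, generate_records
from fastqprep.trimming import (
    AdapterSpec,
    enumerate_mismatch_variants,
    hamming_distance,
    strip_adapter,
    trim_left,
    trim_right,
)

from conftest import rec


class TestEndTrims:
    def test_trim_left_shortens_sequence_and_quality(self):
        r = trim_left(rec("ACGTAC", [10, 11, 12, 13, 14, 15]), 2)
        assert r.sequence == "GTAC"
        assert r.quality == rec("GTAC", [12, 13, 14, 15]).quality

    def test_trim_right_mirrors(self):
        assert trim_right(rec("ACGTAC"), 2).sequence == "ACGT"

    def test_zero_is_identity(self):
        r = rec("ACGT")
        assert trim_left(r, 0) is r and trim_right(r, 0) is r

    def test_saturates_to_empty(self):
        r = trim_left(rec("ACG"), 5)
        assert r.sequence == "" and r.quality == ""

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            trim_left(rec("ACGT"), -1)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10), st.integers(0, 10))
    def test_disjoint_end_trims_commute(self, a, b):
        r = rec("ACGTACGTACGTACGTACGT", list(range(20)))
        if a + b <= len(r.sequence):
            assert trim_right(trim_left(r, a), b) == trim_left(trim_right(r, b), a)

    def test_8_plus_8_reduces_every_length_by_16(self):
        records, _ = generate_records(FixtureSpec(n_reads=300, seed=41))
        for r in records:
            assert len(r.sequence) > 16
            out = trim_right(trim_left(r, 8), 8)
            assert len(out.sequence) == len(r.sequence) - 16
            assert len(out.quality) == len(out.sequence)


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,d", [("TAG", "AAG", 1), ("TAG", "TAA", 1), ("TAG", "TAG", 0), ("TAG", "tag", 0)]
    )
    def test_values(self, a, b, d):
        assert hamming_distance(a, b) == d

    def test_distribution_over_all_3mers(self):
        # brute force: distances from TAG over all 64 3-mers
        hist = {0: 0, 1: 0, 2: 0, 3: 0}
        for kmer in map("".join, product("ACGT", repeat=3)):
            hist[hamming_distance(kmer, "TAG")] += 1
        assert hist == {0: 1, 1: 9, 2: 27, 3: 27}

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            hamming_distance("AC", "ACG")


class TestMismatchEnumeration:
    def test_tag_one_mismatch_is_nine(self):
        variants = enumerate_mismatch_variants("TAG", 1)
        assert len(variants) == 9
        assert {"AAG", "TAA"} <= variants
        assert "TAG" not in variants  # exactly distance 1

    def test_zero_mismatch_is_self(self):
        assert enumerate_mismatch_variants("TAG", 0) == {"TAG"}

    def test_acgt_two_mismatches(self):
        assert len(enumerate_mismatch_variants("ACGT", 2)) == 54  # C(4,2)*3^2

    @pytest.mark.parametrize("adapter", ["TA", "TAG", "ACGT", "AACGTA"])
    def test_closed_form_count_and_exact_distance(self, adapter):
        for k in range(len(adapter)):
            vs = enumerate_mismatch_variants(adapter, k)
            assert len(vs) == comb(len(adapter), k) * 3**k
            assert all(hamming_distance(v, adapter) == k for v in vs)

    def test_out_of_range_k_rejected(self):
        with pytest.raises(ValueError):
            enumerate_mismatch_variants("TAG", 3)

    def test_budget_match_equals_enumeration_union(self):
        """distance(window) <= m  <=>  window in union of exact-k variant sets."""
        adapter, m = "ACGT", 2
        union = set()
        for j in range(m + 1):
            union |= enumerate_mismatch_variants(adapter, j)
        for window in map("".join, product("ACGT", repeat=4)):
            assert (hamming_distance(window, adapter) <= m) == (window in union)


class TestStripAdapter:
    def test_one_mismatch_left_match(self):
        out, hit = strip_adapter(rec("AAGCCCC"), AdapterSpec("TAG", "left", 1))
        assert hit and out.sequence == "CCCC"
        assert len(out.quality) == 4

    def test_two_mismatches_no_match(self):
        r = rec("GGGCCCC")
        out, hit = strip_adapter(r, AdapterSpec("TAG", "left", 1))
        assert not hit and out == r

    def test_right_side_anchoring(self):
        out, hit = strip_adapter(rec("CCCCTAG"), AdapterSpec("TAG", "right", 0))
        assert hit and out.sequence == "CCCC"

    def test_internal_occurrence_not_stripped(self):
        r = rec("CTAGCC")
        out, hit = strip_adapter(r, AdapterSpec("TAG", "left", 0))
        assert not hit and out == r

    def test_read_shorter_than_adapter_never_matches(self):
        r = rec("TA")
        out, hit = strip_adapter(r, AdapterSpec("TAG", "left", 1))
        assert not hit and out == r

    def test_n_counts_as_mismatch(self):
        _, hit = strip_adapter(rec("NAGCC"), AdapterSpec("TAG", "left", 0))
        assert not hit
        _, hit = strip_adapter(rec("NAGCC"), AdapterSpec("TAG", "left", 1))
        assert hit

    def test_matched_fraction_equals_planted_fraction_at_mis0(self):
        ad = AdapterSpec("ACGTACGT", "left", 0)
        records, manifest = generate_records(
            FixtureSpec(n_reads=1000, adapter=ad, adapter_fraction=0.5, seed=77)
        )
        hits = [strip_adapter(r, ad)[1] for r in records]
        assert hits == [e.has_adapter for e in manifest]

    def test_idempotent_at_mis0_for_non_self_overlapping_adapter(self):
        ad = AdapterSpec("TAGC", "left", 0)
        records, _ = generate_records(
            FixtureSpec(n_reads=200, adapter=ad, adapter_fraction=0.5, seed=9)
        )
        for r in records:
            once, _ = strip_adapter(r, ad)
            twice, hit2 = strip_adapter(once, ad)
            # the generator guarantees no read hides a second adapter copy
            assert not hit2 and twice == once

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            AdapterSpec("", "left", 0)
        with pytest.raises(ValueError):
            AdapterSpec("TAG", "left", 3)
        with pytest.raises(ValueError):
            AdapterSpec("TAG", "middle", 0)
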