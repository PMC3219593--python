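from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dna, random_mems
from oracles import brute_force_mems, exhaustive_chain_gain
from recoil.encoder import (
    GainModel,
    MODE_EXPLICIT,
    MODE_FORWARD,
    MODE_REVCOMP,
    MemMatch,
    chain_gain,
    chain_mems,
    encode_read,
    find_mems,
    trim_to_follow,
)
from recoil.sequence import reverse_complement

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


def assert_mems_are_exact_and_maximal(source: str, dest: str, mems: list[MemMatch]) -> None:
    for m in mems:
        s, d, n = m.start_in_source, m.start_in_dest, m.length
        assert source[s : s + n] == dest[d : d + n]
        if s > 0 and d > 0:
            assert source[s - 1] != dest[d - 1]
        if s + n < len(source) and d + n < len(dest):
            assert source[s + n] != dest[d + n]


class TestFindMems:
    def test_toy_first_pair(self):
        assert find_mems("ACCGTTA", "GTTAGCA", 4) == [MemMatch(3, 0, 4)]

    def test_toy_second_pair(self):
        assert find_mems("GTTAGCA", "CCCTTAG", 4) == [MemMatch(1, 3, 4)]

    def test_identical_strings(self):
        # aperiodic string: the only k-mer-sharing diagonal is the main one
        assert find_mems("ACGGTTAC", "ACGGTTAC", 4) == [MemMatch(0, 0, 8)]

    def test_no_shared_seeds(self):
        assert find_mems("AAAA", "CCCC", 3) == []

    def test_matches_brute_force_on_random_pairs(self):
        rng = random.Random(99)
        for _ in range(200):
            ls, ld = rng.randint(30, 120), rng.randint(30, 120)
            # low-entropy alphabet so long shared substrings are common
            source = random_dna(rng, ls, "ACG")
            dest = random_dna(rng, ld, "ACG")
            got = find_mems(source, dest, 5)
            assert set(got) == brute_force_mems(source, dest, 5)
            assert_mems_are_exact_and_maximal(source, dest, got)

    @given(dna, dna, st.integers(2, 6))
    def test_property_equals_brute_force(self, source, dest, k):
        assert set(find_mems(source, dest, k)) == brute_force_mems(source, dest, k)


class TestTrimToFollow:
    def test_disjoint_untouched(self):
        assert trim_to_follow(MemMatch(10, 10, 5), MemMatch(0, 0, 5)) == MemMatch(10, 10, 5)

    def test_dest_overlap_trimmed(self):
        assert trim_to_follow(MemMatch(10, 3, 6), MemMatch(0, 0, 5)) == MemMatch(12, 5, 4)

    def test_source_overlap_trimmed(self):
        assert trim_to_follow(MemMatch(3, 10, 6), MemMatch(0, 0, 5)) == MemMatch(5, 12, 4)

    def test_swallowed_returns_none(self):
        assert trim_to_follow(MemMatch(1, 1, 3), MemMatch(0, 0, 10)) is None


class TestChainMems:
    model = GainModel(letter_cost=2, mem_record_cost=10)

    def test_single_profitable_mem(self):
        mems = [MemMatch(0, 0, 12)]
        assert chain_mems(mems, self.model) == mems

    def test_all_unprofitable_yields_empty_chain(self):
        mems = [MemMatch(0, 0, 3), MemMatch(10, 10, 4)]
        assert chain_mems(mems, self.model) == []

    def test_two_small_compatible_beat_one_conflicting(self):
        mems = [MemMatch(0, 0, 10), MemMatch(20, 20, 10), MemMatch(5, 18, 11)]
        chain = chain_mems(mems, self.model)
        assert chain == [MemMatch(0, 0, 10), MemMatch(20, 20, 10)]

    def test_matches_exhaustive_subset_oracle(self):
        rng = random.Random(123)
        for _ in range(120):
            mems = random_mems(rng, rng.randint(1, 10), span=80, max_len=20)
            model = GainModel(letter_cost=2, mem_record_cost=rng.choice([6, 10, 16, 20]))
            chain = chain_mems(mems, model)
            assert chain_gain(chain, model) == exhaustive_chain_gain(mems, model)
            # returned chain is strictly increasing and non-overlapping
            for prev, cur in zip(chain, chain[1:]):
                assert cur.start_in_dest >= prev.dest_end
                assert cur.start_in_source >= prev.source_end

    def test_chained_mems_remain_exact_matches(self):
        rng = random.Random(7)
        for _ in range(50):
            source = random_dna(rng, 80, "ACG")
            dest = random_dna(rng, 80, "ACG")
            chain = chain_mems(find_mems(source, dest, 4), GainModel.for_k(4))
            for m in chain:
                assert source[m.start_in_source : m.source_end] == dest[m.start_in_dest : m.dest_end]


class TestGainSymmetry:
    def test_savings_symmetric_for_random_pairs(self):
        """Encoding s2 against s1 saves the same space as s1 against s2."""
        rng = random.Random(321)
        model = GainModel(letter_cost=2, mem_record_cost=12)
        for _ in range(50):
            s1 = random_dna(rng, rng.randint(40, 90), "ACG")
            s2 = random_dna(rng, rng.randint(40, 90), "ACG")
            g12 = chain_gain(chain_mems(find_mems(s1, s2, 5), model), model)
            g21 = chain_gain(chain_mems(find_mems(s2, s1, 5), model), model)
            assert g12 == g21


class TestEncodeRead:
    def test_child_equals_parent(self):
        enc = encode_read("ACGTACGTAC", "ACGTACGTAC", 4)
        assert enc.mode == MODE_FORWARD
        assert enc.mems == [MemMatch(0, 0, 10)]
        assert enc.plaintext == ""

    def test_child_is_revcomp_of_parent(self):
        parent = "ACGTTGCAGGT"
        enc = encode_read(reverse_complement(parent), parent, 4)
        assert enc.mode == MODE_REVCOMP
        assert enc.mems == [MemMatch(0, 0, len(parent))]

    def test_unrelated_child_explicit(self):
        enc = encode_read("AAAAAAAAAA", "CCCCCCCCCC", 4)
        assert enc.mode == MODE_EXPLICIT
        assert enc.plaintext == "AAAAAAAAAA"
        assert enc.mems == []

    def test_toy_example_one_mem_three_letters(self):
        enc = encode_read("GTTAGCA", "ACCGTTA", 4, GainModel.for_k(4))
        assert enc.read_len == 7
        assert enc.mode == MODE_FORWARD
        assert enc.mems == [MemMatch(3, 0, 4)]
        assert enc.plaintext == "GCA"

    def test_coverage_accounting(self):
        enc = encode_read("GGGACGTACGTAGG", "TTACGTACGTATT", 4)
        assert sum(m.length for m in enc.mems) + len(enc.plaintext) == enc.read_len


class TestGainModel:
    @pytest.mark.parametrize("cost,expected_min", [(20, 10), (16, 8), (7, 4)])
    def test_min_profitable_matches_cost(self, cost, expected_min):
        model = GainModel(letter_cost=2, mem_record_cost=cost)
        assert model.min_profitable_mem == expected_min
        assert model.gain(expected_min) >= 0
        assert model.gain(expected_min - 1) < 0

    def test_default_threshold_is_seed_length(self):
        assert GainModel.for_k(10).min_profitable_mem == 10
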