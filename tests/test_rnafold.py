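"""Folding, duplex and shuffle cores against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (dinuc_counts, enumerate_dinuc_permutations,
                      oracle_fold_mfe)
from exomir.io import revcomp
from exomir.rnafold import (FoldInputError, _PAIR_NAMES, dinucleotide_shuffle,
                            duplex_mfe, fold_energy, fold_mfe,
                            load_stack_table, randfold_pvalue)

STACKS = load_stack_table()


def _stack(a, b, c, d):
    """Energy of stacking pair (c,d) on pair (a,b), read from the table."""
    return STACKS[_PAIR_NAMES.index(a + b), _PAIR_NAMES.index(c + d)]


class TestFold:
    def test_homopolymer_has_no_structure(self):
        result = fold_mfe("AAAAAAAAAA")
        assert result.energy == 0.0
        assert result.pairs == []
        assert result.structure == "." * 10

    def test_simple_stem_matches_enumeration(self):
        seq = "GGGGAAAACCCC"
        result = fold_mfe(seq)
        assert result.energy == pytest.approx(oracle_fold_mfe(seq))
        assert result.pairs == [(0, 11), (1, 10), (2, 9), (3, 8)]

    def test_energy_never_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), int(rng.integers(5, 60))))
            assert fold_energy(seq) <= 0.0

    def test_agrees_with_exhaustive_enumeration(self):
        """MFE equality against full structure enumeration, length <= 15."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(6, 16))
            seq = "".join(rng.choice(list("ACGT"), n))
            assert fold_energy(seq) == pytest.approx(oracle_fold_mfe(seq)), seq

    def test_structure_is_consistent_with_energy(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), 40))
            result = fold_mfe(seq)
            assert len(result.structure) == len(seq)
            assert result.structure.count("(") == len(result.pairs)
            # pairs are nested and hairpin loops hold >= 3 nt
            for i, j in result.pairs:
                assert j - i > 3
            assert (result.energy == 0.0) == (not result.pairs)

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(FoldInputError):
            fold_mfe("ACGUX_ACG")

    def test_n_bases_stay_unpaired(self):
        assert fold_energy("GGGGNNNNCCCC" + "N" * 5) <= 0.0


class TestDuplex:
    def test_perfect_complement_equals_hand_summed_stacks(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = "".join(rng.choice(list("ACGT"), 20))
            result = duplex_mfe(x, revcomp(x))
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            expected = sum(
                _stack(x[i], comp[x[i]], x[i + 1], comp[x[i + 1]])
                for i in range(19)
            )
            assert result.energy == pytest.approx(expected)
            assert len(result.pairing) == 20

    def test_unpairable_sequences_give_zero(self):
        result = duplex_mfe("AAAA", "AAAA")
        assert result.energy == 0.0
        assert result.pairing == []

    def test_extension_by_complementary_base_never_weakens(self):
        rng = np.random.default_rng(6)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(10):
            x = "".join(rng.choice(list("ACGT"), 15))
            e_short = duplex_mfe(x, revcomp(x)).energy
            extra = "ACGT"[int(rng.integers(4))]
            x2 = x + extra
            e_long = duplex_mfe(x2, comp[extra] + revcomp(x)).energy
            assert e_long <= e_short

    def test_perfect_complement_is_optimal_among_equal_length_targets(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            x = "".join(rng.choice(list("ACGT"), 15))
            best = duplex_mfe(x, revcomp(x)).energy
            y = "".join(rng.choice(list("ACGT"), 15))
            assert best <= duplex_mfe(x, y).energy + 1e-9


class TestShuffle:
    def test_dinucleotide_counts_and_endpoints_preserved(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), int(rng.integers(5, 80))))
            out = dinucleotide_shuffle(seq, int(rng.integers(1000)))
            assert dinuc_counts(out) == dinuc_counts(seq)
            assert (out[0], out[-1]) == (seq[0], seq[-1])

    @pytest.mark.parametrize("seq", ["ACGT", "AACGT", "ACGTGC", "AAAAAA", "ATATAT"])
    def test_output_within_brute_force_enumerated_set(self, seq):
        valid = enumerate_dinuc_permutations(seq)
        for trial in range(20):
            assert dinucleotide_shuffle(seq, trial) in valid

    def test_homopolymer_is_fixed_point(self):
        assert dinucleotide_shuffle("AAAAAA", 1) == "AAAAAA"

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=3, max_size=60),
           st.integers(min_value=0, max_value=10_000))
    def test_shuffle_property_holds_for_arbitrary_sequences(self, seq, seed):
        out = dinucleotide_shuffle(seq, seed)
        assert dinuc_counts(out) == dinuc_counts(seq)
        assert sorted(out) == sorted(seq)  # mononucleotides too

    def test_deterministic_under_fixed_seed(self):
        seq = "ACGTTGCAAGCTTACGGATCGT"
        assert dinucleotide_shuffle(seq, 42) == dinucleotide_shuffle(seq, 42)


class TestRandfold:
    HAIRPIN = ("GCATTAGACCGTTGAATCGA" + "TTAGGCCATAAGTT"
               + revcomp("GCATTAGACCGTTGAATCGA"))

    def test_homopolymer_pvalue_is_one(self):
        assert randfold_pvalue("A" * 30, 50, 1) == 1.0

    def test_strong_hairpin_is_significant(self):
        assert randfold_pvalue(self.HAIRPIN, 199, 1) <= 0.05

    def test_pvalue_stable_across_seeds_within_sampling_error(self):
        p1 = randfold_pvalue(self.HAIRPIN, 199, 1)
        p2 = randfold_pvalue(self.HAIRPIN, 199, 2)
        assert abs(p1 - p2) <= 0.05

    def test_pvalue_bounds(self):
        p = randfold_pvalue("ACGTTACGATGCAGTTCAAT", 19, 0)
        assert 0.0 < p <= 1.0
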