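"""Rank intersection, per-round calls, mode combination, corrections."""

from collections import Counter
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strlnr import (GenotyperConfig, JointEntry, LNRDataset, LNREntry,
                    RoundGenotype, StrLocus, build_lnr, call_round,
                    combine_rounds, intersect_round, lengths_to_repeats,
                    secondary_correction)
from strlnr.genotyper import GenotypeCall

CFG = GenotyperConfig()
LEN_CFG = GenotyperConfig(intersect_mode="length")


def _ds(entries, round_index=1, source="seed-match"):
    return LNRDataset("T", round_index, source,
                      [LNREntry(l, c, r) for l, c, r in entries])


class TestIntersectLengthMode:
    """The strict equal-length reading: same length in both datasets with a
    small rank difference."""

    def test_close_ranks_retained(self):
        d1 = _ds([(36, 90, 1), (40, 10, 2)])
        d2 = _ds([(30, 50, 1), (36, 40, 2)], source="alignment")
        joint = intersect_round(d1, d2, LEN_CFG)
        assert [(j.length, j.count) for j in joint] == [(36, 90)]

    def test_rank_difference_bound_is_exclusive(self):
        d1 = _ds([(36, 90, 1)])
        d2 = _ds([(31, 50, 1), (32, 40, 2), (33, 30, 3), (36, 20, 4)],
                 source="alignment")
        assert intersect_round(d1, d2, LEN_CFG) == []  # |1-4| = 3, not < 3

    def test_identical_datasets_fully_retained(self):
        d1 = _ds([(36, 50, 1), (40, 30, 2), (32, 5, 3)])
        d2 = _ds([(36, 50, 1), (40, 30, 2), (32, 5, 3)], source="alignment")
        assert [j.length for j in intersect_round(d1, d2, LEN_CFG)] == [36, 40, 32]

    def test_seed_context_normalizes_alignment_spans(self):
        d1 = _ds([(36, 90, 1)])
        d2 = _ds([(96, 80, 1)], source="alignment")  # 36 + 2*30 seed context
        joint = intersect_round(d1, d2, LEN_CFG, seed_context=60)
        assert [(j.length, j.rank_d2) for j in joint] == [(36, 1)]


class TestIntersectRankMode:
    """Default reading: dataset2 bounds the rank depth of credible dataset1
    classes via the minimum rank difference."""

    def test_minimum_rank_difference_window(self):
        d1 = _ds([(36, 90, 1), (40, 60, 2), (29, 10, 3), (52, 5, 4), (61, 1, 5)])
        d2 = _ds([(30, 100, 1), (31, 12, 2)], source="alignment")
        joint = intersect_round(d1, d2, CFG)
        # ranks 1..4 are within <3 of some dataset2 rank (max 2); rank 5 is not
        assert [j.length for j in joint] == [36, 40, 29, 52]

    def test_empty_dataset_yields_empty_joint(self):
        d1 = _ds([(36, 90, 1)])
        empty = LNRDataset("T", 1, "alignment", [])
        assert intersect_round(d1, empty, CFG) == []
        assert intersect_round(empty, d1, CFG) == []

    def test_joint_carries_dataset1_counts(self):
        d1 = _ds([(36, 90, 1)])
        d2 = _ds([(36, 40, 1)], source="alignment")
        [j] = intersect_round(d1, d2, CFG)
        assert (j.count, j.d2_count) == (90, 40)


class TestCallRound:
    def _call(self, counts):
        joint = [JointEntry(30 + 2 * i, c, i + 1, 1) for i, c in enumerate(counts)]
        return call_round(joint, "T", 1, CFG)

    def test_dominant_top_yields_single_allele(self):
        rg = self._call([90, 20])  # ratio 4.5 > 3
        assert rg.alleles == [(30, 90)]

    def test_comparable_counts_yield_two_alleles(self):
        rg = self._call([60, 40])  # ratio 1.5 <= 3
        assert rg.alleles == [(30, 60), (32, 40)]

    def test_single_entry_single_allele(self):
        assert self._call([7]).alleles == [(30, 7)]

    def test_empty_joint_abstains(self):
        assert call_round([], "T", 1, CFG) is None

    def test_boundary_ratio_is_exclusive(self):
        rg = self._call([90, 30])  # exactly 3x is NOT > 3
        assert len(rg.alleles) == 2


def _round(alleles, idx=1):
    return RoundGenotype("T", idx, sorted(alleles))


class TestCombineRounds:
    def test_dominant_mode_with_pooled_ratio_is_homozygous(self):
        rounds = [_round([(36, 100)], i) for i in range(1, 9)]
        rounds += [_round([(36, 50), (40, 20)], i) for i in (9, 10)]
        call = combine_rounds(rounds, CFG)
        assert call.zygosity == "homozygous" and call.allele_lengths == [36]
        assert call.rounds_agreeing == 8 and call.rounds_informative == 10

    def test_balanced_two_allele_mode_is_heterozygous(self):
        rounds = [_round([(36, 50), (48, 45)], i) for i in range(1, 11)]
        call = combine_rounds(rounds, CFG)
        assert call.zygosity == "heterozygous"
        assert call.allele_lengths == [36, 48]
        assert call.support == [500, 450]

    def test_single_round_passes_through(self):
        call = combine_rounds([_round([(36, 10), (42, 9)])], CFG)
        assert call.allele_lengths == [36, 42] and call.zygosity == "heterozygous"

    def test_all_rounds_abstained_is_no_call(self):
        call = combine_rounds([None, None], CFG)
        assert call.zygosity == "no-call" and call.reason == "insufficient evidence"

    def test_mode_ratio_threshold_is_inclusive(self):
        # pooled supports 300 vs exactly 100: ratio 3 >= 3 -> homozygous
        rounds = [_round([(36, 100), (40, 33)], i) for i in (1, 2)]
        rounds += [_round([(36, 100), (40, 34)], 3)]
        call = combine_rounds(rounds, CFG)
        assert call.zygosity == "homozygous" and call.allele_lengths == [36]

    @given(st.lists(
        st.lists(st.tuples(st.sampled_from([30, 33, 36, 39]), st.integers(1, 40)),
                 min_size=1, max_size=2, unique_by=lambda t: t[0]),
        min_size=1, max_size=3))
    @settings(max_examples=300, deadline=None)
    def test_equivalence_with_enumeration_oracle(self, round_alleles):
        rounds = [_round(a, i) for i, a in enumerate(round_alleles, 1)]
        call = combine_rounds(rounds, CFG)
        key, zyg, supports = _combine_oracle(round_alleles, CFG)
        assert tuple(call.allele_lengths) == key
        assert call.zygosity == zyg
        assert call.support == supports


def _combine_oracle(round_alleles, cfg):
    """Naive re-derivation of the mode/ratio logic by full enumeration."""
    keys = [tuple(sorted(l for l, _ in alleles)) for alleles in round_alleles]
    votes = Counter(keys)
    candidates = []
    for key in set(keys):
        pooled = {}
        for alleles, k in zip(round_alleles, keys):
            if k == key:
                for l, c in alleles:
                    pooled[l] = pooled.get(l, 0) + c
        candidates.append((votes[key], sum(pooled.values()), key, pooled))
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
    _, _, key, pooled = candidates[0]
    if len(key) == 1:
        return key, "homozygous", [pooled[key[0]]]
    top, second = sorted(pooled.values(), reverse=True)
    if second and top / second >= cfg.mode_ratio:
        major = max(pooled, key=lambda l: (pooled[l], -l))
        return (major,), "homozygous", [pooled[major]]
    return key, "heterozygous", [pooled[l] for l in key]


class TestSecondaryCorrection:
    def _call(self, pairs, zygosity="heterozygous"):
        return GenotypeCall("T", [l for l, _ in pairs], zygosity,
                            [s for _, s in pairs])

    def test_order_of_magnitude_minor_is_demoted(self):
        call = secondary_correction(self._call([(36, 1000), (40, 80)]), CFG)
        assert call.zygosity == "homozygous"
        assert call.allele_lengths == [36] and call.corrected

    def test_comparable_supports_unchanged(self):
        call = secondary_correction(self._call([(36, 300), (40, 200)]), CFG)
        assert call.allele_lengths == [36, 40] and not call.corrected

    def test_homozygous_input_is_a_no_op(self):
        call = secondary_correction(self._call([(36, 500)], "homozygous"), CFG)
        assert call.allele_lengths == [36] and not call.corrected


class TestLengthsToRepeats:
    LOCUS = StrLocus("c", 100, 130, "T", "ATC", 10)

    def _call(self, lengths):
        return GenotypeCall("T", list(lengths), "heterozygous" if len(lengths) > 1
                            else "homozygous", [10] * len(lengths))

    def test_on_ladder_lengths(self):
        call = lengths_to_repeats(self._call([36]), self.LOCUS)
        assert call.allele_repeats == [12] and not call.flags

    def test_reference_length_maps_to_reference_repeats(self):
        assert lengths_to_repeats(self._call([30]), self.LOCUS).allele_repeats == [10]

    def test_off_ladder_length_rounded_and_flagged(self):
        call = lengths_to_repeats(self._call([35]), self.LOCUS)
        assert call.allele_repeats == [12]  # 11.67 rounds to 12
        assert call.flags == ["off-ladder:35"]

    @pytest.mark.parametrize("length", range(24, 43))
    def test_flag_fires_exactly_off_ladder(self, length):
        call = lengths_to_repeats(self._call([length]), self.LOCUS)
        assert bool(call.flags) == ((length - 30) % 3 != 0)

    def test_negative_repeats_void_the_call(self):
        locus = StrLocus("c", 100, 130, "T", "ATC", 10)
        call = lengths_to_repeats(self._call([1]), locus)
        # 1 bp is ~9.7 units below reference: repeat count 0 is allowed,
        # but a length far below zero units is not
        assert call.allele_repeats == [0] or call.zygosity == "no-call"

    def test_deeply_negative_length_is_no_call(self):
        locus = StrLocus("c", 100, 160, "T", "ATC", 10)
        call = lengths_to_repeats(self._call([0]), locus)
        assert call.zygosity == "no-call" and "negative" in call.reason
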