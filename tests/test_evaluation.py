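"""Tests for neighbor annotation, GQ-ranked discordance and trio statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasedsv import (
    CallRecord,
    SVRecord,
    TrioCall,
    canonical_trio_pattern,
    count_neighbors,
    discordance_by_gq_threshold,
    discordance_topn,
    enumerate_canonical_patterns,
    is_mendelian_error,
    mendel_curve,
    stratify_by_parent_pattern,
)
from phasedsv.evaluation import parent_stratum

genotype = st.integers(0, 2)


def transmission_oracle(p1, p2, child):
    """Brute-force enumeration of the 2x2 allele transmissions."""
    gametes = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    return all(a + b != child for a in gametes[p1] for b in gametes[p2])


def dels(*starts, svlen=100):
    return [SVRecord(f"sv{i}", "chr1", s, "DEL", svlen) for i, s in enumerate(starts)]


class TestCountNeighbors:
    def test_pair_within_radius(self):
        # intervals [1000,1100] and [1600,1700]: gap 500 <= 1000
        assert count_neighbors(dels(1000, 1600)) == [1, 1]

    def test_pair_beyond_radius(self):
        # gap 1500 - 1100 + ... => [1000,1100] vs [2600,2700]: gap 1500
        assert count_neighbors(dels(1000, 2600)) == [0, 0]

    def test_cluster_plus_isolated(self):
        svs = dels(1000, 1500, 2000, 10_000)
        brute = []
        for i, a in enumerate(svs):
            c = 0
            for j, b in enumerate(svs):
                if i == j:
                    continue
                gap = max(b.start0 - a.end0, a.start0 - b.end0, 0)
                if gap <= 1000:
                    c += 1
            brute.append(c)
        assert count_neighbors(svs) == brute == [2, 2, 2, 0]

    def test_insertions_are_points(self):
        ins = SVRecord("i", "chr1", 3000, "INS", 500)
        d = SVRecord("d", "chr1", 1000, "DEL", 1000)  # ends at 2000; gap to 3000 is 1000
        assert count_neighbors([d, ins]) == [1, 1]

    def test_chromosomes_are_independent(self):
        a = SVRecord("a", "chr1", 1000, "DEL", 100)
        b = SVRecord("b", "chr2", 1000, "DEL", 100)
        assert count_neighbors([a, b]) == [0, 0]


def make_calls(specs):
    return [CallRecord(f"sv{i}", call, truth, gq) for i, (call, truth, gq) in enumerate(specs)]


class TestDiscordance:
    def test_all_correct(self):
        calls = make_calls([(1, 1, 30)] * 10)
        assert discordance_topn(calls, 10, seed=0) == 0.0

    def test_full_selection_is_seed_independent(self):
        calls = make_calls([(1, 0, 30), (1, 1, 10), (0, 0, 20), (2, 2, 5)])
        vals = {discordance_topn(calls, 4, seed=s) for s in range(10)}
        assert vals == {0.25}

    def test_boundary_bin_sampling_space(self):
        """GQ 30 x5 all correct, GQ 10 x5 with 3 errors; top-7 takes the five
        GQ-30 calls plus 2 sampled from the low bin: k/7 errors, k in {0,1,2},
        with mean over seeds near (3/5)*2/7."""
        specs = [(1, 1, 30)] * 5 + [(1, 0, 10)] * 3 + [(1, 1, 10)] * 2
        calls = make_calls(specs)
        observed = [discordance_topn(calls, 7, seed=s) for s in range(400)]
        assert set(observed) <= {0.0, 1 / 7, 2 / 7}
        assert np.mean(observed) == pytest.approx((3 / 5) * 2 / 7, abs=0.03)

    def test_selecting_more_than_called_raises(self):
        with pytest.raises(ValueError, match="top"):
            discordance_topn(make_calls([(1, 1, 30)]), 2, seed=0)

    def test_missing_calls_do_not_rank(self):
        calls = make_calls([(1, 1, 30), (None, 1, 0), (0, 1, 20)])
        assert discordance_topn(calls, 2, seed=0) == 0.5

    def test_threshold_zero_includes_all_called(self):
        calls = make_calls([(1, 1, 0), (0, 1, 10), (None, 0, 0)])
        disc, rate = discordance_by_gq_threshold(calls, 0)
        assert disc == 0.5 and rate == pytest.approx(2 / 3)

    def test_threshold_above_max_reports_missing(self):
        calls = make_calls([(1, 1, 30)])
        disc, rate = discordance_by_gq_threshold(calls, 99)
        assert disc is None and rate == 0.0

    def test_discordance_decreases_with_threshold(self):
        # errors concentrated at low GQ
        specs = [(1, 0, 5), (1, 0, 10), (1, 1, 20), (1, 1, 30), (0, 0, 40), (2, 2, 50)]
        calls = make_calls(specs)
        discs = [discordance_by_gq_threshold(calls, t)[0] for t in (0, 15, 35)]
        assert discs == sorted(discs, reverse=True)
        assert discs[0] == pytest.approx(2 / 6) and discs[2] == 0.0


class TestTrioPatterns:
    @pytest.mark.parametrize(
        "trio,expected",
        [
            ((2, 2, 2), "000"),  # alt count 6: polarized to the minor allele
            ((0, 0, 0), "000"),
            ((2, 0, 1), "021"),  # tie at 3 alt alleles; both orientations agree
            ((0, 1, 2), "012"),
            ((1, 0, 2), "012"),  # parent order dropped
            ((2, 1, 0), "012"),  # flip of the previous
        ],
    )
    def test_canonical_hand_values(self, trio, expected):
        assert canonical_trio_pattern(*trio) == expected

    def test_enumeration_collapses_27_to_10(self):
        n_ordered, canon = enumerate_canonical_patterns()
        assert n_ordered == 27 and len(canon) == 10

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(genotype, genotype, genotype)
    def test_canonicalization_invariances(self, p1, p2, c):
        pattern = canonical_trio_pattern(p1, p2, c)
        # idempotent
        assert canonical_trio_pattern(*(int(d) for d in pattern)) == pattern
        # parent swap
        assert canonical_trio_pattern(p2, p1, c) == pattern
        # global allele flip
        assert canonical_trio_pattern(2 - p1, 2 - p2, 2 - c) == pattern

    def test_invalid_genotype_rejected(self):
        with pytest.raises(ValueError, match="genotype"):
            canonical_trio_pattern(0, 3, 0)


class TestMendelianError:
    def test_agrees_with_transmission_oracle_on_all_27(self):
        for trio in itertools.product((0, 1, 2), repeat=3):
            assert is_mendelian_error(*trio) == transmission_oracle(*trio), trio

    @pytest.mark.parametrize("child", [0, 1, 2])
    def test_double_het_parents_never_error(self, child):
        assert not is_mendelian_error(1, 1, child)

    @pytest.mark.parametrize(
        "trio,expected",
        [((0, 0, 1), True), ((0, 2, 1), False), ((0, 2, 0), True), ((0, 2, 2), True)],
    )
    def test_hand_values(self, trio, expected):
        assert is_mendelian_error(*trio) is expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(genotype, genotype, genotype)
    def test_invariant_under_canonicalization(self, p1, p2, c):
        canon = tuple(int(d) for d in canonical_trio_pattern(p1, p2, c))
        assert is_mendelian_error(p1, p2, c) == is_mendelian_error(*canon)


def make_trios(specs):
    return [TrioCall(f"sv{i}", tuple(g), tuple(q)) for i, (g, q) in enumerate(specs)]


class TestMendelCurve:
    def test_all_consistent(self):
        trios = make_trios([((0, 0, 0), (30, 30, 30))] * 4)
        assert mendel_curve(trios, 4, seed=0) == 0.0

    def test_single_error_at_lowest_min_gq(self):
        trios = make_trios(
            [
                ((0, 1, 1), (50, 40, 60)),
                ((1, 1, 2), (45, 50, 55)),
                ((0, 0, 0), (60, 35, 50)),
                ((0, 0, 2), (20, 30, 25)),  # Mendelian error, min GQ 20
            ]
        )
        assert mendel_curve(trios, 4, seed=0) == 0.25
        assert mendel_curve(trios, 2, seed=0) == 0.0

    def test_incomplete_trios_excluded(self):
        trios = make_trios(
            [((0, 0, 0), (30, 30, 30)), ((None, 0, 2), (99, 99, 99)), ((0, 0, 2), (10, 10, 10))]
        )
        assert mendel_curve(trios, 2, seed=0) == 0.5


class TestParentStratification:
    @pytest.mark.parametrize(
        "parents,stratum",
        [((0, 0), "00"), ((2, 2), "00"), ((2, 0), "02"), ((0, 2), "02"),
         ((1, 2), "het"), ((1, 1), "het"), ((0, 1), "het")],
    )
    def test_stratum_assignment(self, parents, stratum):
        assert parent_stratum(*parents) == stratum

    def test_same_hom_stratum_errors_iff_child_not_hom_matching(self):
        for parents in ((0, 0), (2, 2)):
            for child in (0, 1, 2):
                err = is_mendelian_error(*parents, child)
                assert err == (child != parents[0])

    def test_discordant_hom_stratum_errors_iff_child_not_het(self):
        for child in (0, 1, 2):
            assert is_mendelian_error(0, 2, child) == (child != 1)

    def test_shares_and_rates(self):
        trios = make_trios(
            [
                ((0, 0, 0), (9, 9, 9)),
                ((0, 0, 1), (9, 9, 9)),  # error in "00"
                ((0, 2, 1), (9, 9, 9)),
                ((1, 2, 0), (9, 9, 9)),  # error in "het"
            ]
        )
        strata = stratify_by_parent_pattern(trios)
        assert strata["00"] == (0.5, 0.5)
        assert strata["02"] == (0.25, 0.0)
        assert strata["het"] == (0.25, 1.0)
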