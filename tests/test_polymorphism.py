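"""Tests 1-3, unit estimation, quality grading and best-measurement ranking."""
import numpy as np
import pytest

from ptrcat.align import AlignmentResult
from ptrcat.model import (GenomicInterval, PolymorphismMeasurement,
                          TargetPlacement, TRCandidate)
from ptrcat.polymorphism import (classify_quality, estimate_target_units,
                                 measure_polymorphism, round_half_away,
                                 select_best_measurement, thresholds_for)
from ptrcat.polymorphism import test1 as prefix_test
from ptrcat.polymorphism import test2 as residual_test


def plant_substitutions(s, k, rng):
    out = list(s)
    for i in rng.choice(len(s), size=k, replace=False):
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


def pure_measure(motif, a, b):
    S, T = motif * a, motif * b
    tr = TRCandidate(GenomicInterval("ref", 0, len(S)), motif, float(a), S)
    pl = TargetPlacement(status="PLACED", target_sequence_id="t",
                         target_span=(0, max(1, len(T))), target_sequence=T)
    return measure_polymorphism(tr, pl)


class TestThresholdFormulas:
    @pytest.mark.parametrize("n,m,k,k_prime", [
        (30, 36, 3, 0),     # residual 6: min(30, 5) = 5 -> 0
        (30, 70, 3, 3),     # residual 40: min(30, 39) = 30 -> 3
        (9, 12, 0, 0),      # floor forces zero tolerance below n = 10
        (10, 11, 1, 0),     # m = n + 1: k' = floor(0.1 * 0) = 0
        (50, 50, 5, 0),
    ])
    def test_values(self, n, m, k, k_prime):
        th = thresholds_for(n, m)
        assert (th.k, th.k_prime) == (k, k_prime)


class TestTest1:
    def test_pure_expansion_prefix(self):
        th = thresholds_for(30, 36)
        assert prefix_test("CAG" * 10, "CAG" * 12, th)

    def test_exactly_k_substitutions_pass_k_plus_one_fail(self, rng):
        for n in range(10, 61, 10):
            S = "".join(rng.choice(list("ACGT"), size=n))
            T = S + "ACGT"
            th = thresholds_for(n, len(T))
            at_k = plant_substitutions(S, th.k, rng) + "ACGT"
            over = plant_substitutions(S, th.k + 1, rng) + "ACGT"
            assert prefix_test(S, at_k, th)
            assert not prefix_test(S, over, th)

    def test_zero_tolerance_below_ten(self, rng):
        S = "ACGTACGTA"  # n = 9 -> k = 0
        T = plant_substitutions(S, 1, rng) + "AC"
        assert not prefix_test(S, T, thresholds_for(9, len(T)))


class TestTest2:
    def test_pure_residual(self):
        S, T = "CAG" * 10, "CAG" * 12
        assert residual_test(S, T, thresholds_for(30, 36))

    def test_garbage_residual_fails(self):
        S = "CAG" * 10
        T = S + "GGGGGG"
        assert not residual_test(S, T, thresholds_for(30, 36))

    def test_single_base_residual_matching_first_base(self):
        S = "CAGCAGCAGC"
        T = S + "C"  # residual = first base of S
        assert residual_test(S, T, thresholds_for(10, 11))

    def test_vacuous_when_no_residual(self):
        S = "CAGCAGCAGC"
        assert residual_test(S, S, thresholds_for(10, 10))


class TestEstimateUnits:
    @pytest.mark.parametrize("m1,m2,motif,expected", [
        (30, 6, 3, 12),
        (30, 0, 3, 10),
        (20, 3, 7, 3),   # round(23/7) = round(3.29) = 3
    ])
    def test_rounded_ratio(self, m1, m2, motif, expected):
        assert estimate_target_units(m1, m2, motif) == expected

    def test_small_motif_rejected(self):
        with pytest.raises(ValueError):
            estimate_target_units(10, 0, 1)

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(2.5) == 3
        assert round_half_away(-2.5) == -3
        assert round_half_away(2.4) == 2
        assert round_half_away(-2.4) == -2


def aln(qspan, sspan, matches=None):
    m = matches if matches is not None else qspan[1] - qspan[0]
    return AlignmentResult(matches=m, score=m, query_span=qspan,
                           subject_span=sspan)


class TestClassifyQuality:
    def test_adjacent_and_overlapping_is_high(self):
        # T spans touch at 30; S2 is a prefix of S1
        assert classify_quality(aln((0, 30), (0, 30)),
                                aln((0, 6), (30, 36)), 3) == "high"

    def test_small_gap_is_medium(self):
        assert classify_quality(aln((0, 30), (0, 30)),
                                aln((0, 10), (32, 42)), 5) == "medium"

    def test_disjoint_s_spans_is_low(self):
        assert classify_quality(aln((10, 30), (0, 20)),
                                aln((0, 6), (20, 26)), 3) == "low"

    def test_large_gap_is_low(self):
        assert classify_quality(aln((0, 30), (0, 30)),
                                aln((0, 10), (45, 55)), 5) == "low"

    def test_small_motif_short_aln2_needs_majority_matches(self):
        # motif 3 <= 4, second alignment 6 < 8 bp, gap of 2: the relaxed
        # grade additionally needs > half the shorter aligned string matched
        weak = aln((0, 6), (32, 38), matches=3)
        ok = aln((0, 6), (32, 38), matches=4)
        assert classify_quality(aln((0, 30), (0, 30)), weak, 3) == "low"
        assert classify_quality(aln((0, 30), (0, 30)), ok, 3) == "medium"


class TestMeasurePolymorphism:
    def test_pure_expansion(self):
        m = pure_measure("CAG", 10, 12)
        assert (m.delta_units, m.units_target, m.quality) == (2, 12, "high")
        assert (m.matches_aln1, m.matches_aln2) == (30, 6)

    def test_pure_contraction_role_swap(self):
        m = pure_measure("CAG", 12, 10)
        assert (m.delta_units, m.units_target, m.quality) == (-2, 10, "high")

    def test_equal_lengths_not_polymorphic(self):
        m = pure_measure("CAG", 10, 10)
        assert m.delta_units == 0 and m.quality == "high"

    def test_expansion_beyond_doubling(self):
        m = pure_measure("ACGT", 3, 33)
        assert (m.delta_units, m.units_target) == (30, 33)

    def test_pure_repeat_sweep_subset(self):
        for motif in ("AC", "CAGTT", "ACGTACGTACGTACG"):
            for a, b in ((2, 3), (2, 10), (5, 6), (10, 40), (39, 40)):
                m = pure_measure(motif, a, b)
                assert m.delta_units == b - a and m.quality == "high"

    def test_antisymmetry_on_pure_pairs(self):
        for a, b in ((3, 7), (5, 11), (10, 12)):
            assert (pure_measure("ACG", a, b).delta_units
                    == -pure_measure("ACG", b, a).delta_units)

    def test_failed_test_forces_low_quality(self):
        S = "CAG" * 10
        T = S + "GGGGGG"  # residual breaks Test 2
        tr = TRCandidate(GenomicInterval("ref", 0, 30), "CAG", 10.0, S)
        pl = TargetPlacement(status="PLACED", target_sequence_id="t",
                             target_span=(0, 36), target_sequence=T)
        m = measure_polymorphism(tr, pl)
        assert not m.test2_passed and m.quality == "low"

    def test_complete_loss(self):
        m = pure_measure("CAGTT", 8, 0)
        assert (m.delta_units, m.units_target, m.quality) == (-8, 0, "high")

    def test_unplaced_rejected(self):
        tr = TRCandidate(GenomicInterval("ref", 0, 30), "CAG", 10.0, "CAG" * 10)
        with pytest.raises(ValueError):
            measure_polymorphism(tr, TargetPlacement(status="LOW_IDENTITY"))


def meas(delta, quality, span=(0, 10), seq_id="t"):
    return PolymorphismMeasurement(
        delta_units=delta, units_target=max(0, 10 + delta), matches_aln1=1,
        matches_aln2=0, quality=quality, target_sequence_id=seq_id,
        target_span=span)


class TestSelectBest:
    def test_quality_dominates_delta(self):
        best = select_best_measurement([meas(1, "high"), meas(5, "medium")])
        assert best.quality == "high" and best.delta_units == 1

    def test_absolute_delta_breaks_quality_ties(self):
        best = select_best_measurement([meas(1, "high"), meas(-3, "high")])
        assert best.delta_units == -3

    def test_leftmost_breaks_full_ties(self):
        a = meas(2, "high", span=(50, 60))
        b = meas(2, "high", span=(5, 15))
        assert select_best_measurement([a, b]) == b

    def test_singleton(self):
        m = meas(0, "low")
        assert select_best_measurement([m]) == m

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_measurement([])
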