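"""Catalog matching, stratified ratios with bootstrap CIs, delta histogram,
windowed SNP correlation."""
import numpy as np
import pytest

from ptrcat.candidates import jaccard_coefficient
from ptrcat.finishing import build_catalog
from ptrcat.model import GenomicInterval, PolymorphismMeasurement
from ptrcat.stats import (delta_histogram, match_catalogs, ptr_tr_ratio,
                          snp_density_correlation)


def meas(delta, quality="high", genome="g1"):
    return PolymorphismMeasurement(
        delta_units=delta, units_target=max(0, 10 + delta), matches_aln1=1,
        matches_aln2=0, quality=quality, target_genome=genome,
        target_sequence_id="t", target_span=(0, 10))


def catalog_from(candidates, deltas):
    return build_catalog([(tr, {"A": [meas(d)]})
                          for tr, d in zip(candidates, deltas)])


class TestMatchCatalogs:
    def test_self_match_at_j_one(self, candidate_factory):
        cat = [candidate_factory(100 * i, 100 * i + 30) for i in range(8)]
        assert match_catalogs(cat, cat, 1.0) == (8, 0)

    def test_disjoint(self, candidate_factory):
        a = [candidate_factory(0, 30)]
        b = [candidate_factory(500, 530)]
        assert match_catalogs(a, b, 0.5) == (0, 1)

    def test_planted_fraction(self, candidate_factory):
        src = [candidate_factory(100 * i, 100 * i + 40) for i in range(10)]
        # 6 targets overlap their source at Jaccard 36/44 ~ 0.82 > 0.7
        tgt = [candidate_factory(100 * i + 4, 100 * i + 44) for i in range(6)]
        assert match_catalogs(src, tgt, 0.7) == (6, 4)
        # brute-force cross-check of the planted overlap values
        for s, t in zip(src, tgt):
            assert jaccard_coefficient(s.interval, t.interval) == \
                pytest.approx(36 / 44)

    def test_overlap_count_non_increasing_in_j(self, candidate_factory):
        rng = np.random.default_rng(4)
        src = [candidate_factory(200 * i, 200 * i + 50) for i in range(30)]
        tgt = [candidate_factory(200 * i + int(rng.integers(0, 30)),
                                 200 * i + 50 + int(rng.integers(0, 30)))
               for i in range(30)]
        counts = [match_catalogs(src, tgt, j)[0]
                  for j in (0.5, 0.7, 0.9, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_asymmetric_roles(self, candidate_factory):
        src = [candidate_factory(0, 30), candidate_factory(100, 130)]
        tgt = [candidate_factory(0, 30)]
        assert match_catalogs(src, tgt, 0.9) == (1, 1)
        assert match_catalogs(tgt, src, 0.9) == (1, 0)


class TestPtrTrRatio:
    def _setup(self, candidate_factory, n, polymorphic_flags):
        cands = [candidate_factory(100 * i, 100 * i + 20, motif="AC",
                                   units=10) for i in range(n)]
        deltas = [2 if f else 0 for f in polymorphic_flags]
        return cands, catalog_from(cands, deltas)

    def test_extreme_ratios_have_degenerate_cis(self, candidate_factory):
        cands, cat0 = self._setup(candidate_factory, 100, [False] * 100)
        (s0,) = ptr_tr_ratio(cands, cat0, [(2, 2)], [(5, 15)], 200, seed=1)
        assert s0.ratio == 0.0 and s0.ci95 == (0.0, 0.0)
        _, cat1 = self._setup(candidate_factory, 100, [True] * 100)
        (s1,) = ptr_tr_ratio(cands, cat1, [(2, 2)], [(5, 15)], 200, seed=1)
        assert s1.ratio == 1.0 and s1.ci95 == (1.0, 1.0)

    def test_empty_stratum_emitted_as_missing(self, candidate_factory):
        cands, cat = self._setup(candidate_factory, 10, [True] * 10)
        (s,) = ptr_tr_ratio(cands, cat, [(7, 10)], [(5, 15)], 200, seed=1)
        assert s.n_tr == 0 and s.ratio is None and s.ci95 is None

    def test_ci_contains_point_ratio_and_is_deterministic(self,
                                                          candidate_factory):
        rng = np.random.default_rng(9)
        flags = rng.random(200) < 0.2
        cands, cat = self._setup(candidate_factory, 200, flags)
        (a,) = ptr_tr_ratio(cands, cat, [(2, 2)], [(5, 15)], 300, seed=42)
        (b,) = ptr_tr_ratio(cands, cat, [(2, 2)], [(5, 15)], 300, seed=42)
        assert a == b
        assert a.ci95[0] <= a.ratio <= a.ci95[1]

    def test_binomial_coverage(self, candidate_factory):
        """The bootstrap CI of a 20% polymorphism rate covers 0.2 in most
        seeded replications."""
        rng = np.random.default_rng(77)
        covered = 0
        reps = 60
        for _ in range(reps):
            flags = rng.random(400) < 0.2
            cands, cat = self._setup(candidate_factory, 400, flags)
            (s,) = ptr_tr_ratio(cands, cat, [(2, 2)], [(5, 15)], 200,
                                seed=int(rng.integers(2**31)))
            covered += s.ci95[0] <= 0.2 <= s.ci95[1]
        assert covered >= 0.88 * reps


class TestDeltaHistogram:
    def test_counts(self, candidate_factory):
        cands = [candidate_factory(100 * i, 100 * i + 20) for i in range(3)]
        cat = catalog_from(cands, [1, 1, -2])
        assert delta_histogram(cat) == {1: 2, -2: 1}

    def test_empty(self):
        assert delta_histogram([]) == {}

    def test_zero_never_present(self, candidate_factory):
        cands = [candidate_factory(100 * i, 100 * i + 20) for i in range(4)]
        cat = catalog_from(cands, [0, 2, 0, -1])
        assert 0 not in delta_histogram(cat)

    def test_symmetric_construction(self, candidate_factory):
        cands = [candidate_factory(100 * i, 100 * i + 20) for i in range(6)]
        cat = catalog_from(cands, [1, -1, 3, -3, 2, -2])
        h = delta_histogram(cat)
        assert all(h[d] == h[-d] for d in (1, 2, 3))


class TestSnpCorrelation:
    def _catalog(self, candidate_factory, units_per_window, window=5000):
        cands = []
        for w, units in enumerate(units_per_window):
            start = w * window + 100
            cands.append(candidate_factory(start, start + 2 * units,
                                           motif="AC", units=units))
        return catalog_from(cands, [2] * len(cands))

    def test_perfect_positive_correlation(self, candidate_factory):
        units = list(range(5, 25))
        cat = self._catalog(candidate_factory, units)
        snps = {"chr1": [w * 5000 + i for w, u in enumerate(units)
                         for i in range(u)]}
        rho, p = snp_density_correlation(cat, snps, 5000)
        assert rho == pytest.approx(1.0)
        assert p < 1e-6

    def test_perfect_anticorrelation(self, candidate_factory):
        units = list(range(5, 25))
        cat = self._catalog(candidate_factory, units)
        snps = {"chr1": [w * 5000 + i for w, u in enumerate(units)
                         for i in range(30 - u)]}
        rho, _ = snp_density_correlation(cat, snps, 5000)
        assert rho == pytest.approx(-1.0)

    def test_independent_noise_has_small_rho(self, candidate_factory):
        rng = np.random.default_rng(13)
        ok = 0
        for _ in range(20):
            units = [int(u) for u in rng.integers(5, 30, size=400)]
            cat = self._catalog(candidate_factory, units)
            snps = {"chr1": sorted(int(x) for x in
                                   rng.integers(0, 400 * 5000, size=2000))}
            rho, _ = snp_density_correlation(cat, snps, 5000)
            ok += abs(rho) < 0.12
        assert ok >= 18

    def test_too_few_windows_signalled(self, candidate_factory):
        cat = self._catalog(candidate_factory, [5, 6])
        with pytest.raises(ValueError):
            snp_density_correlation(cat, {"chr1": [1, 2]}, 5000)

    def test_window_size_bounds(self, candidate_factory):
        cat = self._catalog(candidate_factory, [5] * 10)
        with pytest.raises(ValueError):
            snp_density_correlation(cat, {}, 1000)
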