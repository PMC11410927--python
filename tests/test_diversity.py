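"""Diversity statistics against brute-force and independently coded oracles."""

import itertools
import math

import numpy as np
import pytest

from vectorpop.diversity import (
    cohort_diversity_summary,
    harmonic,
    nucleotide_diversity,
    tajima_constants,
    tajimas_d,
    watterson_theta,
)
from vectorpop.io import CohortPartition, HaplotypeMatrix
from vectorpop.simulate import NeutralWindowSpec, simulate_coalescent_window

from conftest import make_window, random_window


def brute_pi(alleles: np.ndarray) -> float:
    """Mean pairwise difference by explicit pair enumeration."""
    n = alleles.shape[1]
    pairs = list(itertools.combinations(range(n), 2))
    total = sum(int((alleles[:, i] != alleles[:, j]).sum()) for i, j in pairs)
    return total / len(pairs)


def oracle_tajimas_d(alleles: np.ndarray) -> float:
    """Independent Tajima's D: brute-force pi, explicit constant formulas."""
    n = alleles.shape[1]
    p = alleles.mean(axis=1)
    S = int(((p > 0) & (p < 1)).sum())
    if S == 0:
        return math.nan
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1 * a1 + a2)
    return (brute_pi(alleles) - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestNucleotideDiversity:
    def test_single_site_half_frequency(self):
        # alleles {0,0,1,1}: 4 of 6 pairs differ -> pi = 2/3
        w = make_window(np.array([[0, 0, 1, 1]]))
        assert nucleotide_diversity(w) == pytest.approx(2 / 3, abs=1e-12)

    def test_monomorphic_window_is_zero(self):
        w = make_window(np.zeros((5, 6)))
        assert nucleotide_diversity(w) == 0.0

    def test_matches_pair_enumeration(self, rng):
        for _ in range(5):
            w = random_window(rng, 20, 10)
            assert nucleotide_diversity(w) == pytest.approx(brute_pi(w.alleles), abs=1e-12)

    def test_needs_two_haplotypes(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(make_window(np.zeros((1, 0))))

    def test_invariant_to_column_order_and_relabeling(self, rng):
        w = random_window(rng, 15, 8)
        perm = rng.permutation(8)
        assert nucleotide_diversity(make_window(w.alleles[:, perm])) == pytest.approx(
            nucleotide_diversity(w), abs=1e-12
        )
        assert nucleotide_diversity(make_window(1 - w.alleles)) == pytest.approx(
            nucleotide_diversity(w), abs=1e-12
        )


class TestWattersonTheta:
    def test_harmonic_scaling(self, rng):
        # S = 5, n = 10 -> 5 / 2.828968 = 1.7674
        alleles = np.zeros((5, 10), dtype=np.int8)
        alleles[:, 0] = 1  # five singleton sites
        assert watterson_theta(make_window(alleles)) == pytest.approx(1.7674, abs=1e-4)

    def test_no_segregating_sites(self):
        assert watterson_theta(make_window(np.ones((3, 6)))) == 0.0

    def test_two_haplotypes_theta_equals_s(self):
        alleles = np.array([[0, 1], [1, 0], [0, 1]])
        assert watterson_theta(make_window(alleles)) == 3.0

    def test_relabeling_invariance(self, rng):
        w = random_window(rng, 12, 6)
        assert watterson_theta(make_window(1 - w.alleles)) == watterson_theta(w)


class TestTajimasD:
    def test_zero_when_pi_equals_scaled_s(self):
        # n = 4 (a1 = 11/6): 8 singleton + 3 doubleton sites give
        # pi = 8 * 1/2 + 3 * 2/3 = 6 = S / a1 exactly, so D = 0
        singles = [np.eye(1, 4, i % 4, dtype=np.int8)[0] for i in range(8)]
        doubles = [np.array([1, 1, 0, 0], dtype=np.int8)] * 3
        w = make_window(np.array(singles + doubles))
        assert tajimas_d(w) == pytest.approx(0.0, abs=1e-9)

    def test_two_haplotypes_degenerate_variance_flagged(self):
        alleles = np.array([[0, 1], [1, 0], [0, 1]])
        assert math.isnan(tajimas_d(make_window(alleles)))

    def test_negative_after_sweep_like_window(self):
        # one common haplotype plus singleton-bearing copies: excess of rare alleles
        alleles = np.zeros((8, 10), dtype=np.int8)
        for i in range(8):
            alleles[i, i % 3] = 1
        d = tajimas_d(make_window(alleles))
        assert d < 0

    def test_undefined_without_segregating_sites(self):
        assert math.isnan(tajimas_d(make_window(np.zeros((4, 6)))))

    def test_agrees_with_independent_oracle(self, rng):
        for _ in range(20):
            w = random_window(rng, 25, 12)
            d = tajimas_d(w)
            d_oracle = oracle_tajimas_d(w.alleles)
            if math.isnan(d_oracle):
                assert math.isnan(d)
            else:
                assert d == pytest.approx(d_oracle, abs=1e-9)

    def test_constants_sane(self):
        c = tajima_constants(10)
        assert c["a1"] == pytest.approx(harmonic(9))
        assert all(v > 0 for k, v in c.items() if k in ("e1", "e2"))


class TestCohortSummary:
    @pytest.fixture
    def structured_cohorts(self):
        # shared site axis: cohort "swept" is a low-diversity (sweep-reduced)
        # copy of the same window's haplotypes, as after strong selection
        from vectorpop.simulate import SweepSpec, inject_sweep

        hm = simulate_coalescent_window(NeutralWindowSpec(40, 60.0, seed=1, span=(0, 10**6)))
        swept = inject_sweep(hm, SweepSpec(0.9, 0.0), seed=2)
        alleles = np.hstack([hm.alleles, swept.alleles])
        samples = [f"div{i}" for i in range(20)] + [f"swp{i}" for i in range(20)]
        union = HaplotypeMatrix(alleles, samples, hm.variants)
        part = CohortPartition({"diverse": samples[:20], "swept": samples[20:]})
        return union, part

    def test_identical_cohorts_identical_summaries(self, rng):
        w = random_window(rng, 300, 12)
        res_a = cohort_diversity_summary(
            w, CohortPartition({"a": w.samples[:3]}), window_size_snps=100
        )
        res_b = cohort_diversity_summary(w, CohortPartition({"b": w.samples[:3]}), window_size_snps=100)
        for ra, rb in zip(res_a, res_b):
            assert ra.point == rb.point and ra.statistic == rb.statistic

    def test_jackknife_ci_contains_point(self, rng):
        w = random_window(rng, 600, 10)
        res = cohort_diversity_summary(
            w, CohortPartition({"a": w.samples}), window_size_snps=100
        )
        for r in res:
            assert r.ci_low <= r.point <= r.ci_high
            assert r.n_windows == 6

    def test_diversity_ordering_recovered(self, structured_cohorts):
        union, part = structured_cohorts
        res = cohort_diversity_summary(union, part, window_size_snps=50)
        by = {(r.cohort, r.statistic): r.point for r in res}
        assert by[("diverse", "pi")] > by[("swept", "pi")]
        assert by[("diverse", "theta_w")] > by[("swept", "theta_w")]

    def test_few_windows_flagged_unreliable(self, rng):
        w = random_window(rng, 120, 8)
        res = cohort_diversity_summary(w, CohortPartition({"a": w.samples}), window_size_snps=60)
        assert all(not r.ci_reliable for r in res)


def test_pi_and_theta_agree_on_neutral_replicates():
    # both estimate theta: their means over replicates coincide within 3 SE
    reps = 400
    diffs = []
    for i in range(reps):
        hm = simulate_coalescent_window(NeutralWindowSpec(10, 10.0, seed=i))
        diffs.append(nucleotide_diversity(hm) - watterson_theta(hm))
    diffs = np.array(diffs)
    se = diffs.std(ddof=1) / np.sqrt(reps)
    assert abs(diffs.mean()) < 3 * se
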