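"""Garud H statistics, windowed scan and peak calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vectorpop.selection import HScanResult, call_peaks, garud_h, h_scan, haplotype_spectrum
from vectorpop.simulate import NeutralWindowSpec, SweepSpec, inject_sweep, simulate_coalescent_window

from conftest import make_window, random_window


def string_spectrum(alleles: np.ndarray) -> np.ndarray:
    """Brute-force haplotype spectrum via string-keyed counting."""
    counts: dict[str, int] = {}
    for j in range(alleles.shape[1]):
        key = "".join(map(str, alleles[:, j]))
        counts[key] = counts.get(key, 0) + 1
    return np.sort(np.array(list(counts.values())) / alleles.shape[1])[::-1]


class TestHaplotypeSpectrum:
    def test_monomorphic_and_two_class_windows(self):
        assert list(haplotype_spectrum(make_window(np.zeros((3, 4))))) == [1.0]
        two = make_window(np.array([[0, 0, 1, 1], [0, 0, 1, 1]]))
        assert list(haplotype_spectrum(two)) == [0.5, 0.5]

    def test_matches_string_counting(self, rng):
        for _ in range(10):
            w = random_window(rng, 8, 12)
            np.testing.assert_allclose(
                haplotype_spectrum(w), string_spectrum(w.alleles), atol=1e-15
            )


class TestGarudH:
    @pytest.mark.parametrize(
        "spectrum,expected",
        [
            ([0.5, 0.5], (0.5, 1.0, 1.0, 0.5)),
            ([1.0], (1.0, 1.0, 1.0, 0.0)),
            ([0.25, 0.25, 0.25, 0.25], (0.25, 0.375, 0.625, 0.75)),
        ],
    )
    def test_worked_spectra(self, spectrum, expected):
        h1, h12, h123, h2h1 = garud_h(np.array(spectrum))
        assert (h1, h12, h123) == pytest.approx(expected[:3], abs=1e-12)
        assert h2h1 == pytest.approx(expected[3], abs=1e-12)

    def test_rejects_unsorted_or_unnormalised(self):
        with pytest.raises(ValueError):
            garud_h(np.array([0.2, 0.8]))
        with pytest.raises(ValueError):
            garud_h(np.array([0.5, 0.4]))

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=20))
    def test_ordering_invariant(self, raw):
        p = np.sort(np.array(raw) / np.sum(raw))[::-1]
        h1, h12, h123, h2h1 = garud_h(p)
        assert 0 < h1 <= h12 <= h123 <= 1.0 + 1e-12
        assert 0 <= h2h1 < 1

    def test_formula_against_direct_sums(self, rng):
        for _ in range(100):
            w = random_window(rng, 6, 10)
            p = haplotype_spectrum(w)
            h1, h12, h123, h2h1 = garud_h(p)
            pad = np.concatenate([p, [0, 0, 0]])
            assert h1 == pytest.approx(float((pad**2).sum()), abs=1e-12)
            assert h12 == pytest.approx(
                float((pad[0] + pad[1]) ** 2 + (pad[2:] ** 2).sum()), abs=1e-12
            )
            assert h123 == pytest.approx(
                float((pad[:3].sum()) ** 2 + (pad[3:] ** 2).sum()), abs=1e-12
            )
            assert h2h1 == pytest.approx(float((h1 - pad[0] ** 2) / h1), abs=1e-12)

    def test_h12_is_one_iff_at_most_two_haplotypes(self, rng):
        w = make_window(np.array([[0, 0, 1, 1], [0, 0, 1, 1]]))
        assert garud_h(haplotype_spectrum(w))[1] == pytest.approx(1.0)
        three = make_window(np.array([[0, 0, 1, 1], [0, 1, 0, 1]]))
        assert garud_h(haplotype_spectrum(three))[1] < 1.0


class TestHScan:
    def test_window_arithmetic(self, rng):
        w = random_window(rng, 2000, 10)
        res = h_scan(w, window_size=1000)
        assert len(res) == 2
        assert all(not r.flagged for r in res)
        # trailing 600-SNP remainder (>= half a window) is kept and flagged
        res2 = h_scan(random_window(rng, 2600, 10), window_size=1000)
        assert len(res2) == 3 and res2[-1].flagged and res2[-1].n_snps == 600
        # a 300-SNP remainder is dropped
        res3 = h_scan(random_window(rng, 2300, 10), window_size=1000)
        assert len(res3) == 2

    def test_too_few_snps_warns_and_returns_empty(self, rng):
        with pytest.warns(UserWarning):
            assert h_scan(random_window(rng, 10, 6), window_size=100) == []

    def test_sweep_window_h12_exceeds_f_squared(self):
        hm = simulate_coalescent_window(NeutralWindowSpec(20, 20.0, seed=5))
        swept = inject_sweep(hm, SweepSpec(0.6, 0.0), seed=6)
        res = h_scan(swept, window_size=max(2, swept.n_sites))
        assert res[0].h12 > 0.36  # (p1 + p2)^2 >= f^2 by construction

    def test_neutral_background_h12_is_low(self):
        # the scan's peak/background contrast rests on a low neutral median
        vals = []
        for i in range(200):
            hm = simulate_coalescent_window(NeutralWindowSpec(50, 40.0, seed=20_000 + i))
            if hm.n_sites >= 2:
                vals.append(h_scan(hm, window_size=hm.n_sites)[0].h12)
        assert np.median(vals) < 0.1

    def test_mean_h12_separates_sweep_from_neutral(self):
        # even with residual mutation eroding exact identity (eps = 0.01 per
        # site per copy), the mean H12 over paired replicates is well above
        # the neutral mean, backing the peak/background interpretation
        neutral, swept = [], []
        for i in range(200):
            hm = simulate_coalescent_window(NeutralWindowSpec(50, 10.0, seed=40_000 + i))
            if hm.n_sites == 0:
                continue
            sw = inject_sweep(hm, SweepSpec(0.6, 0.01), seed=41_000 + i)
            neutral.append(garud_h(haplotype_spectrum(hm))[1])
            swept.append(garud_h(haplotype_spectrum(sw))[1])
        assert np.mean(swept) > np.mean(neutral)

    def test_h12_monotone_in_sweep_fraction(self):
        hm = simulate_coalescent_window(NeutralWindowSpec(30, 30.0, seed=8))
        h12s = []
        for f in (0.0, 0.3, 0.6, 0.9):
            swept = inject_sweep(hm, SweepSpec(f, 0.0), seed=99)
            h12s.append(garud_h(haplotype_spectrum(swept))[1])
        assert all(a <= b + 1e-12 for a, b in zip(h12s, h12s[1:]))


def _mk_result(chrom, start, end, h12):
    return HScanResult(
        cohort="c", chrom=chrom, window_start=start, window_end=end,
        midpoint=(start + end) / 2, h1=h12 / 2, h12=h12, h123=h12, h2_h1=0.1,
        n_snps=100,
    )


class TestCallPeaks:
    def test_no_windows_above_threshold(self):
        res = [_mk_result("1", i * 100 + 1, i * 100 + 100, 0.05) for i in range(5)]
        assert call_peaks(res, 0.1, 2) == []

    def test_single_run_merged_into_one_interval(self):
        h12s = [0.05, 0.3, 0.4, 0.2, 0.05]
        res = [
            _mk_result("1", i * 100 + 1, i * 100 + 100, h) for i, h in enumerate(h12s)
        ]
        peaks = call_peaks(res, 0.1, 2)
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.start, p.end, p.n_windows) == (101, 400, 3)
        assert p.max_h12 == 0.4

    def test_short_runs_and_chromosome_breaks(self):
        res = [
            _mk_result("1", 1, 100, 0.5),
            _mk_result("2", 1, 100, 0.5),  # same H12 but a new chromosome
        ]
        assert call_peaks(res, 0.1, 2) == []
        assert len(call_peaks(res, 0.1, 1)) == 2
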