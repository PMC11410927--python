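"""Windowed diversity statistics: pi, Watterson's theta, Tajima's D.

All three operate on complete phased windows (a :class:`HaplotypeMatrix`).
Nucleotide diversity pi is the exact mean number of pairwise differences,
computed from per-site allele frequencies with the n/(n-1) finite-sample
factor; Watterson's theta scales the segregating-site count by the harmonic
number a1 = sum_{i<n} 1/i; Tajima's D standardises pi - theta_W with the
classic variance constants derived from the sample size. Negative D indicates
an excess of rare alleles, as after a sweep or expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from vectorpop._util import snp_windows
from vectorpop.io import CohortPartition, HaplotypeMatrix

Z95 = 1.959964


@dataclass
class DiversityResult:
    cohort: str
    statistic: str  # pi | theta_w | tajima_d
    point: float
    ci_low: float
    ci_high: float
    n_windows: int
    per_base: bool = False
    ci_reliable: bool = True


def _check_window(window: HaplotypeMatrix) -> None:
    if window.n_haplotypes < 2:
        raise ValueError("diversity statistics need >= 2 haplotypes")


def nucleotide_diversity(window: HaplotypeMatrix, span: int | None = None) -> float:
    """Mean pairwise difference per window (per base if ``span`` bp is given).

    pi = sum_sites n/(n-1) * (1 - p^2 - q^2), identical to enumerating all
    haplotype pairs and averaging their per-pair differences.
    """
    _check_window(window)
    n = window.n_haplotypes
    if window.n_sites == 0:
        return 0.0
    p = window.alleles.mean(axis=1)
    pi = float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1))
    return pi / span if span else pi


def segregating_sites(window: HaplotypeMatrix) -> int:
    if window.n_sites == 0:
        return 0
    p = window.alleles.mean(axis=1)
    return int(np.count_nonzero((p > 0) & (p < 1)))


def harmonic(n: int) -> float:
    """a1 = sum_{i=1}^{n} 1/i."""
    return float(sum(1.0 / i for i in range(1, n + 1)))


def watterson_theta(window: HaplotypeMatrix, span: int | None = None) -> float:
    """theta_W = S / a1 with a1 the (n-1)-th harmonic number."""
    _check_window(window)
    theta = segregating_sites(window) / harmonic(window.n_haplotypes - 1)
    return theta / span if span else theta


def tajima_constants(n: int) -> dict[str, float]:
    """Variance constants for Tajima's D at sample size n haplotypes."""
    a1 = harmonic(n - 1)
    a2 = float(sum(1.0 / i**2 for i in range(1, n)))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(window: HaplotypeMatrix) -> float:
    """Tajima's D; NaN when the window has no segregating sites (undefined)."""
    _check_window(window)
    S = segregating_sites(window)
    if S == 0:
        return math.nan
    c = tajima_constants(window.n_haplotypes)
    pi = nucleotide_diversity(window)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:  # n = 2 degenerates: pi == S/a1 identically, variance 0
        return math.nan
    return (pi - S / c["a1"]) / math.sqrt(var)


_STATS = {
    "pi": lambda w: nucleotide_diversity(w),
    "theta_w": lambda w: watterson_theta(w),
    "tajima_d": tajimas_d,
}


def _jackknife_ci(values: np.ndarray) -> tuple[float, float, float]:
    """Delete-one-window jackknife 95% CI around the mean of ``values``."""
    m = len(values)
    mean = float(values.mean())
    if m < 2:
        return mean, mean, mean
    loo = (values.sum() - values) / (m - 1)
    se = math.sqrt((m - 1) / m * float(np.sum((loo - loo.mean()) ** 2)))
    return mean, mean - Z95 * se, mean + Z95 * se


def cohort_diversity_summary(
    hm: HaplotypeMatrix,
    part: CohortPartition,
    window_size_snps: int = 1000,
    span: int | None = None,
    min_windows_for_ci: int = 5,
) -> list[DiversityResult]:
    """Per-cohort windowed pi / theta_W / Tajima's D with jackknife 95% CIs.

    Statistics are computed per non-overlapping window of
    ``window_size_snps`` SNPs; the point estimate is the mean over windows and
    the CI a delete-one-window jackknife. With fewer than
    ``min_windows_for_ci`` windows the CI is flagged unreliable. ``span``
    gives the per-window bp span for per-base normalisation of pi and theta_W.
    """
    if window_size_snps < 50:
        raise ValueError("window size below 50 SNPs gives unstable windowed statistics")
    results = []
    for name, ids in part.items():
        sub = hm.subset_samples(ids)
        windows = [
            HaplotypeMatrix(
                sub.alleles[a:b], sub.samples, sub.variants.take(np.arange(a, b))
            )
            for a, b, _ in snp_windows(sub.n_sites, window_size_snps)
        ]
        for stat, fn in _STATS.items():
            vals = np.array([fn(w) for w in windows], dtype=float)
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                results.append(
                    DiversityResult(name, stat, math.nan, math.nan, math.nan, 0, bool(span), False)
                )
                continue
            if span and stat in ("pi", "theta_w"):
                vals = vals / span
            point, lo, hi = _jackknife_ci(vals)
            results.append(
                DiversityResult(
                    cohort=name,
                    statistic=stat,
                    point=point,
                    ci_low=lo,
                    ci_high=hi,
                    n_windows=len(vals),
                    per_base=bool(span) and stat in ("pi", "theta_w"),
                    ci_reliable=len(vals) >= min_windows_for_ci,
                )
            )
    return results
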