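"""Garud H-statistics scan over SNP windows of phased haplotypes.

H1 = sum p_i^2 is the expected haplotype homozygosity of a window; H12 merges
the two most frequent haplotypes before squaring, making it sensitive to both
hard sweeps (one high-frequency haplotype) and soft sweeps (two); H123 merges
three. H2/H1 (homozygosity excluding the top haplotype over H1) helps separate
hard from soft sweeps. A sweep raises H12 across contiguous windows, producing
a peak against the neutral background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from vectorpop._util import snp_windows
from vectorpop.io import HaplotypeMatrix


@dataclass
class HScanResult:
    cohort: str
    chrom: str
    window_start: int  # 1-based inclusive bp
    window_end: int
    midpoint: float
    h1: float
    h12: float
    h123: float
    h2_h1: float
    n_snps: int
    flagged: bool = False  # partial trailing window


@dataclass
class Peak:
    chrom: str
    start: int  # 1-based inclusive bp
    end: int
    n_windows: int
    max_h12: float
    max_midpoint: float


def haplotype_spectrum(window: HaplotypeMatrix) -> np.ndarray:
    """Sorted (descending) frequencies of distinct full-window haplotypes."""
    # exact identity over the window: missing data must have been filtered upstream
    _, counts = np.unique(window.alleles.T, axis=0, return_counts=True)
    freqs = np.sort(counts / window.n_haplotypes)[::-1]
    return freqs


def garud_h(spectrum: np.ndarray) -> tuple[float, float, float, float]:
    """(H1, H12, H123, H2/H1) from a sorted haplotype-frequency spectrum."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim != 1 or len(spectrum) == 0:
        raise ValueError("spectrum must be a non-empty 1-D array")
    if np.any(np.diff(spectrum) > 1e-12):
        raise ValueError("spectrum must be sorted in descending order")
    if abs(spectrum.sum() - 1.0) > 1e-8:
        raise ValueError(f"spectrum must sum to 1, got {spectrum.sum()}")
    p = np.concatenate([spectrum, np.zeros(3)])  # treat absent classes as 0
    h1 = float(np.sum(p**2))
    h12 = float((p[0] + p[1]) ** 2 + np.sum(p[2:] ** 2))
    h123 = float((p[0] + p[1] + p[2]) ** 2 + np.sum(p[3:] ** 2))
    h2_h1 = float((h1 - p[0] ** 2) / h1)
    return h1, h12, h123, h2_h1


def h_scan(
    hm: HaplotypeMatrix,
    window_size: int = 1000,
    step: int | None = None,
    cohort: str = "all",
) -> list[HScanResult]:
    """Garud H statistics in moving SNP windows (default non-overlapping).

    A trailing partial window is kept and flagged if it covers at least half
    a window, dropped otherwise; with fewer SNPs than half a window the scan
    returns empty with a warning. The midpoint is the mean of the first and
    last SNP positions in the window.
    """
    results: list[HScanResult] = []
    windows = list(snp_windows(hm.n_sites, window_size, step))
    if not windows:
        warnings.warn(
            f"only {hm.n_sites} SNPs for window size {window_size}; no windows scanned"
        )
        return results
    pos1 = hm.variants.pos1
    chrom_arr = hm.variants.chrom
    for a, b, flagged in windows:
        sub = HaplotypeMatrix(
            hm.alleles[a:b], hm.samples, hm.variants.take(np.arange(a, b))
        )
        h1, h12, h123, h2h1 = garud_h(haplotype_spectrum(sub))
        start, end = int(pos1[a]), int(pos1[b - 1])
        results.append(
            HScanResult(
                cohort=cohort,
                chrom=str(chrom_arr[a]),
                window_start=start,
                window_end=end,
                midpoint=(start + end) / 2.0,
                h1=h1,
                h12=h12,
                h123=h123,
                h2_h1=h2h1,
                n_snps=b - a,
                flagged=flagged,
            )
        )
    return results


def call_peaks(
    results: list[HScanResult],
    threshold: float = 0.1,
    min_contiguous: int = 2,
    value=lambda r: r.h12,
) -> list[Peak]:
    """Maximal runs of >= ``min_contiguous`` consecutive windows with H12 >= threshold.

    Runs are merged into genomic intervals; each peak records its best window.
    The same machinery serves the F_ST scan via the ``value`` accessor.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if min_contiguous < 1:
        raise ValueError("min_contiguous must be >= 1")
    peaks: list[Peak] = []
    run: list[HScanResult] = []

    def close_run() -> None:
        if len(run) >= min_contiguous:
            best = max(run, key=value)
            peaks.append(
                Peak(
                    chrom=run[0].chrom,
                    start=run[0].window_start,
                    end=run[-1].window_end,
                    n_windows=len(run),
                    max_h12=value(best),
                    max_midpoint=best.midpoint,
                )
            )
        run.clear()

    prev_chrom = None
    for r in results:
        v = value(r)
        above = np.isfinite(v) and v >= threshold
        if r.chrom != prev_chrom:
            close_run()
        if above:
            run.append(r)
        else:
            close_run()
        prev_chrom = r.chrom
    close_run()
    return peaks
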