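"""Windowed Hudson F_ST between cohort pairs.

Per site the Hudson estimator (in the Bhatia/Patterson parameterisation) has
numerator N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) and denominator
D = p1(1-p2) + p2(1-p1); per window F_ST is the ratio of averages
sum(N)/sum(D) — never the average of per-site ratios, which is biased. The
finite-sample correction makes the estimator unbiased, so small negative
window values are expected near panmixia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from vectorpop._util import snp_windows
from vectorpop.io import CohortPartition, GenotypeMatrix, allele_counts_by_cohort
from vectorpop.selection import HScanResult, Peak, call_peaks


@dataclass
class FstResult:
    cohort_pair: tuple[str, str]
    chrom: str
    window_start: int  # 1-based inclusive bp
    window_end: int
    midpoint: float
    fst: float  # NaN when the window denominator is zero
    n_snps: int
    flagged: bool = False


def hudson_components(p1, p2, n1, n2):
    """Per-site Hudson numerator and denominator (vectorised).

    ``n1``/``n2`` are called-allele counts; the bias correction is undefined
    below 2 alleles.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 1) or np.any(n2 <= 1):
        raise ValueError("called-allele counts must be >= 2 for the bias correction")
    # grouped so the estimator is bit-exactly symmetric under population exchange
    num = (p1 - p2) ** 2 - (p1 * (1 - p1) / (n1 - 1) + p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def windowed_fst(
    counts1: tuple[np.ndarray, np.ndarray],
    counts2: tuple[np.ndarray, np.ndarray],
    windows: list[tuple[int, int]],
) -> list[tuple[float, int]]:
    """(F_ST, n_snps) per site-index window from per-cohort (alt, called) tables.

    Sites with fewer than 2 called alleles in either cohort are skipped; sites
    monomorphic for the same allele in both cohorts contribute N = D = 0 and
    are excluded from n_snps. A window whose denominator sums to zero yields
    NaN.
    """
    alt1, called1 = (np.asarray(a, dtype=float) for a in counts1)
    alt2, called2 = (np.asarray(a, dtype=float) for a in counts2)
    if alt1.shape != alt2.shape:
        raise ValueError("count tables must be site-aligned")
    usable = (called1 >= 2) & (called2 >= 2)
    p1 = np.divide(alt1, called1, out=np.zeros_like(alt1), where=called1 > 0)
    p2 = np.divide(alt2, called2, out=np.zeros_like(alt2), where=called2 > 0)
    num = np.zeros_like(p1)
    den = np.zeros_like(p1)
    if usable.any():
        num[usable], den[usable] = hudson_components(
            p1[usable], p2[usable], called1[usable], called2[usable]
        )
    informative = usable & (den > 0)
    out = []
    for a, b in windows:
        sl = slice(a, b)
        d_sum = float(den[sl][usable[sl]].sum())
        n_snps = int(informative[sl].sum())
        if d_sum == 0:
            out.append((float("nan"), n_snps))
        else:
            out.append((float(num[sl][usable[sl]].sum()) / d_sum, n_snps))
    return out


def fst_scan(
    gm: GenotypeMatrix,
    part: CohortPartition,
    pair: tuple[str, str],
    window_size_snps: int = 1000,
    step: int | None = 500,
) -> list[FstResult]:
    """Windowed Hudson F_ST between two cohorts over the genotype site axis.

    Windows follow the same SNP-count scheme as the H12 scan (trailing
    half-window kept, flagged). Peaks requiring multiple contiguous windows
    can be called on the result with :func:`fst_peaks`.
    """
    a, b = pair
    for name in pair:
        if len(part[name]) < 2:
            raise ValueError(f"cohort {name!r} has fewer than 2 samples")
    counts = allele_counts_by_cohort(gm, CohortPartition({a: part[a], b: part[b]}))
    windows = list(snp_windows(gm.n_sites, window_size_snps, step))
    vals = windowed_fst(counts[a], counts[b], [(s, e) for s, e, _ in windows])
    pos1 = gm.variants.pos1
    chrom = gm.variants.chrom
    results = []
    for (s, e, flagged), (fst, n_snps) in zip(windows, vals):
        start, end = int(pos1[s]), int(pos1[e - 1])
        results.append(
            FstResult(
                cohort_pair=pair,
                chrom=str(chrom[s]),
                window_start=start,
                window_end=end,
                midpoint=(start + end) / 2.0,
                fst=fst,
                n_snps=n_snps,
                flagged=flagged,
            )
        )
    return results


def fst_peaks(
    results: list[FstResult], threshold: float = 0.1, min_contiguous: int = 2
) -> list[Peak]:
    """Contiguous-window F_ST peaks (isolated single-window spikes are not supported)."""
    proxies = [
        HScanResult(
            cohort="-".join(r.cohort_pair),
            chrom=r.chrom,
            window_start=r.window_start,
            window_end=r.window_end,
            midpoint=r.midpoint,
            h1=0.0,
            h12=r.fst,
            h123=0.0,
            h2_h1=0.0,
            n_snps=r.n_snps,
            flagged=r.flagged,
        )
        for r in results
    ]
    return call_peaks(proxies, threshold=threshold, min_contiguous=min_contiguous)
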