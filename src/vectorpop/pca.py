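"""Genotype PCA for population-structure assessment, one chromosome arm at a time.

Sites are filtered on minor-allele frequency and missingness, dosages are
mean-imputed, centred at twice the alt frequency and scaled by
sqrt(2 p (1 - p)) — unit variance under Hardy–Weinberg — and the sample
coordinates come from a deterministic full SVD, so results carry no seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from vectorpop.io import MISSING, GenotypeMatrix


@dataclass
class PcaResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray
    n_sites_used: int
    n_components_requested: int

    @property
    def degenerate(self) -> bool:
        return self.coordinates.shape[1] < self.n_components_requested


def build_pca_matrix(
    gm: GenotypeMatrix, maf_min: float = 0.01, max_missing: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Centred/scaled dosage matrix (samples x kept sites) and kept-site index.

    Per kept site the dosage g in {0,1,2} (missing -> site mean) becomes
    (g - 2 p) / sqrt(2 p (1 - p)) with p the alt frequency among called
    alleles. Monomorphic sites and sites failing the MAF or missingness
    filters are dropped.
    """
    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    g = gm.genotypes
    called = (g != MISSING).sum(axis=2)  # alleles called per sample
    alt = ((g == 1) & (g != MISSING)).sum(axis=2)
    total_called = called.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt.sum(axis=1) / total_called
    maf = np.minimum(p, 1 - p)
    miss_frac = (called < 2).mean(axis=1)
    keep = (total_called > 0) & (maf >= maf_min) & (maf > 0) & (miss_frac <= max_missing)
    kept = np.flatnonzero(keep)
    if kept.size == 0:
        raise ValueError("no sites pass the MAF/missingness filters")

    dose = alt[kept].astype(float)
    fully_called = called[kept] == 2
    dose[~fully_called] = np.nan
    site_mean = np.nanmean(dose, axis=1)
    nan_r, nan_c = np.nonzero(np.isnan(dose))
    dose[nan_r, nan_c] = site_mean[nan_r]
    pk = p[kept]
    scaled = (dose - 2 * pk[:, None]) / np.sqrt(2 * pk * (1 - pk))[:, None]
    return scaled.T.copy(), kept  # samples x sites


def run_pca(
    matrix: np.ndarray,
    n_components: int = 10,
    sample_ids: list[str] | None = None,
) -> PcaResult:
    """Project samples onto the top principal components of the scaled matrix.

    Components are ordered by decreasing explained variance; each component's
    sign is fixed so its largest-magnitude site loading is positive. With a
    degenerate rank fewer components are returned (``result.degenerate``).
    """
    X = np.asarray(matrix, dtype=float)
    n_samples = X.shape[0]
    if not 1 <= n_components <= n_samples:
        raise ValueError("need samples >= n_components >= 1")
    Xc = X - X.mean(axis=0, keepdims=True)  # centre samples so PCs ignore the mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max() * max(Xc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    k = min(n_components, rank)
    coords = U[:, :k] * s[:k]
    total_var = float((s**2).sum())
    evr = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    for comp in range(k):  # sign convention: dominant loading positive
        j = int(np.argmax(np.abs(Vt[comp])))
        if Vt[comp, j] < 0:
            coords[:, comp] *= -1
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(n_samples)]
    return PcaResult(
        sample_ids=list(sample_ids),
        coordinates=coords,
        explained_variance_ratio=evr,
        n_sites_used=X.shape[1],
        n_components_requested=n_components,
    )


def pca_per_arm(
    gm: GenotypeMatrix,
    n_components: int = 10,
    maf_min: float = 0.01,
    max_missing: float = 0.1,
) -> dict[str, PcaResult]:
    """Run the PCA separately for each chromosome arm present in the genotypes."""
    out: dict[str, PcaResult] = {}
    for chrom in dict.fromkeys(gm.variants.chrom):
        idx = np.flatnonzero(gm.variants.chrom == chrom)
        sub = GenotypeMatrix(gm.genotypes[idx], gm.samples, gm.variants.take(idx))
        matrix, _ = build_pca_matrix(sub, maf_min=maf_min, max_missing=max_missing)
        out[str(chrom)] = run_pca(matrix, n_components=min(n_components, len(gm.samples)), sample_ids=gm.samples)
    return out
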