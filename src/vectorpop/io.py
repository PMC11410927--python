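"""Data model, VCF/metadata ingestion, sample QC and cohort partitioning.

Genotypes are read from VCF 4.x through cyvcf2. Only biallelic SNP records are
retained; multiallelic records are dropped, not split, matching the phased
biallelic-SNP substrate of the windowed statistics. Internally all positions
are 0-based half-open; VCF's 1-based positions are converted on read and
restored on write, and every reported window span is 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # missing allele code in GenotypeMatrix

#: sex assignment bounds on the X:3R modal coverage ratio (closed intervals)
MALE_RATIO = (0.4, 0.6)
FEMALE_RATIO = (0.8, 1.2)


@dataclass
class VariantTable:
    """Site axis of all windowed statistics: biallelic SNPs, one alt each.

    ``pos0`` holds 0-based positions; ``pos1`` exposes the VCF convention.
    Positions are strictly increasing within each chromosome.
    """

    chrom: np.ndarray  # str per site
    pos0: np.ndarray  # int64, 0-based
    ref: np.ndarray  # str per site
    alt: np.ndarray  # str per site

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos0 = np.asarray(self.pos0, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        for c in np.unique(self.chrom):
            p = self.pos0[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def pos1(self) -> np.ndarray:
        return self.pos0 + 1

    @property
    def n_sites(self) -> int:
        return len(self.pos0)

    @property
    def site_index(self) -> np.ndarray:
        return np.arange(self.n_sites)

    def take(self, idx: np.ndarray) -> "VariantTable":
        return VariantTable(self.chrom[idx], self.pos0[idx], self.ref[idx], self.alt[idx])


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 alleles, sites x haplotypes; the substrate of H12 and diversity.

    Every entry is 0 or 1 (no missing data); each sample contributes exactly
    two adjacent columns. ``site_index`` maps rows back into the full
    VariantTable when the matrix was derived from a VCF (phased sites only).
    """

    alleles: np.ndarray  # (S, 2N) int8 in {0,1}
    samples: list[str]
    variants: VariantTable
    site_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (sites x haplotypes)")
        if self.alleles.size and not np.isin(self.alleles, [0, 1]).all():
            raise ValueError("HaplotypeMatrix alleles must be 0/1 with no missing")
        if self.alleles.shape[1] != 2 * len(self.samples):
            raise ValueError(
                f"{self.alleles.shape[1]} haplotype columns for {len(self.samples)} samples;"
                " each sample contributes exactly 2"
            )
        if self.variants.n_sites != self.alleles.shape[0]:
            raise ValueError("variants and alleles disagree on site count")

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    @property
    def sample_of_haplotype(self) -> list[str]:
        return [s for s in self.samples for _ in range(2)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "HaplotypeMatrix":
        col_idx = []
        for sid in sample_ids:
            j = self.samples.index(sid)
            col_idx.extend([2 * j, 2 * j + 1])
        return HaplotypeMatrix(
            self.alleles[:, col_idx], list(sample_ids), self.variants, self.site_index
        )


@dataclass
class GenotypeMatrix:
    """Diploid genotypes, sites x samples x 2 allele indices; missing allowed."""

    genotypes: np.ndarray  # (S, N, 2) int8 in {0, 1, MISSING}
    samples: list[str]
    variants: VariantTable

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must be (sites, samples, 2)")
        if not np.isin(self.genotypes, [0, 1, MISSING]).all():
            raise ValueError("allele index must be 0, 1 or missing")
        if self.genotypes.shape[1] != len(self.samples):
            raise ValueError("samples and genotype columns disagree")
        if self.variants.n_sites != self.genotypes.shape[0]:
            raise ValueError("variants and genotypes disagree on site count")

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def sample_columns(self, sample_ids: Sequence[str]) -> np.ndarray:
        index = {s: j for j, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"sample ids not in genotype matrix: {missing}")
        return np.array([index[s] for s in sample_ids], dtype=np.intp)


@dataclass
class SampleRecord:
    """One sequenced mosquito with its QC covariates; sex is derived, never input."""

    sample_id: str
    site: str
    subsite: str
    cohort: str
    mean_coverage: float
    x_3r_ratio: float
    sex: str = field(default="", init=True)

    def __post_init__(self) -> None:
        if self.mean_coverage < 0:
            raise ValueError(f"mean_coverage must be >= 0, got {self.mean_coverage}")
        if not self.sex:
            self.sex = assign_sex_from_coverage(self.x_3r_ratio)


@dataclass
class CohortPartition:
    """Named, disjoint, non-empty sample-id sets defining the analysis cohorts."""

    cohorts: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for name, ids in self.cohorts.items():
            if not ids:
                raise ValueError(f"cohort {name!r} is empty")
            for sid in ids:
                if sid in seen:
                    raise ValueError(f"sample {sid!r} in both {seen[sid]!r} and {name!r}")
                seen[sid] = name

    @property
    def names(self) -> list[str]:
        return list(self.cohorts)

    def __getitem__(self, name: str) -> list[str]:
        return self.cohorts[name]

    def items(self):
        return self.cohorts.items()

    @classmethod
    def from_samples(cls, samples: Iterable[SampleRecord]) -> "CohortPartition":
        cohorts: dict[str, list[str]] = {}
        for rec in samples:
            cohorts.setdefault(rec.cohort, []).append(rec.sample_id)
        return cls(cohorts)


def assign_sex_from_coverage(x_3r_ratio: float) -> str:
    """Sex from the X:3R modal coverage ratio.

    Ratios in [0.4, 0.6] are male, [0.8, 1.2] female; anything else excludes
    the sample. Bounds are treated as closed intervals.
    """
    if x_3r_ratio < 0:
        raise ValueError(f"coverage ratio must be non-negative, got {x_3r_ratio}")
    if MALE_RATIO[0] <= x_3r_ratio <= MALE_RATIO[1]:
        return "male"
    if FEMALE_RATIO[0] <= x_3r_ratio <= FEMALE_RATIO[1]:
        return "female"
    return "excluded"


def qc_filter_samples(
    samples: Sequence[SampleRecord], min_coverage: float = 10.0
) -> list[SampleRecord]:
    """Drop samples with mean coverage below ``min_coverage`` (>= keeps the boundary)."""
    if min_coverage <= 0:
        raise ValueError(f"min_coverage must be > 0, got {min_coverage}")
    return [s for s in samples if s.mean_coverage >= min_coverage]


def read_sample_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the sample-metadata TSV (sample_id, site, subsite, cohort, mean_coverage, x_3r_ratio)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    required = {"sample_id", "site", "subsite", "cohort", "mean_coverage", "x_3r_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path} lacks columns: {sorted(missing)}")
    return [
        SampleRecord(
            sample_id=row.sample_id,
            site=row.site,
            subsite=row.subsite,
            cohort=row.cohort,
            mean_coverage=float(row.mean_coverage),
            x_3r_ratio=float(row.x_3r_ratio),
        )
        for row in df.itertuples()
    ]


def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    # "chrom" or "chrom:start-end", 1-based inclusive
    if ":" not in region:
        return region, None, None
    chrom, span = region.split(":", 1)
    start_s, end_s = span.split("-", 1)
    return chrom, int(start_s), int(end_s)


def read_phased_vcf(
    path: str | Path, region: str | None = None
) -> tuple[VariantTable, HaplotypeMatrix, GenotypeMatrix]:
    """Read biallelic SNPs from a VCF into the three core containers.

    Unphased or partially missing genotypes stay in the GenotypeMatrix, but a
    site enters the HaplotypeMatrix only if every genotype at it is phased and
    fully called. ``region`` is ``chrom`` or ``chrom:start-end`` (1-based
    inclusive); an absent chromosome yields empty results with a warning.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    want_chrom, want_start, want_end = (None, None, None)
    if region is not None:
        want_chrom, want_start, want_end = _parse_region(region)

    chroms: list[str] = []
    pos0: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    geno_rows: list[np.ndarray] = []
    phased_rows: list[bool] = []
    seen_chroms: set[str] = set()

    for rec_no, v in enumerate(vcf, start=1):
        seen_chroms.add(v.CHROM)
        if want_chrom is not None:
            if v.CHROM != want_chrom:
                continue
            if want_start is not None and not (want_start <= v.POS <= want_end):
                continue
        if len(v.ALT) != 1:
            continue  # multiallelic records are dropped, not split
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue  # SNPs only
        gts = v.genotypes  # [[a1, a2, phased], ...]
        if any(len(g) != 3 for g in gts):
            raise ValueError(
                f"non-diploid GT in {path} at record {rec_no} ({v.CHROM}:{v.POS})"
            )
        arr = np.array([[g[0], g[1]] for g in gts], dtype=np.int8)
        arr[arr < 0] = MISSING
        fully_called = bool((arr != MISSING).all())
        fully_phased = fully_called and all(g[2] for g in gts)
        chroms.append(v.CHROM)
        pos0.append(v.POS - 1)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        geno_rows.append(arr)
        phased_rows.append(fully_phased)

    if want_chrom is not None and want_chrom not in seen_chroms:
        warnings.warn(f"chromosome {want_chrom!r} absent from {path}; returning empty result")

    n_sites = len(pos0)
    variants = VariantTable(
        np.array(chroms, dtype=object),
        np.array(pos0, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
    )
    geno = (
        np.stack(geno_rows)
        if geno_rows
        else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    gm = GenotypeMatrix(geno, samples, variants)

    phased_mask = np.array(phased_rows, dtype=bool)
    hap_idx = np.flatnonzero(phased_mask)
    hap_alleles = (
        geno[hap_idx].reshape(len(hap_idx), 2 * len(samples))
        if n_sites
        else np.empty((0, 2 * len(samples)), dtype=np.int8)
    )
    hm = HaplotypeMatrix(hap_alleles, samples, variants.take(hap_idx), site_index=hap_idx)
    return variants, hm, gm


def allele_counts_by_cohort(
    gm: GenotypeMatrix, part: CohortPartition
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per cohort, per-site (alt count, called-allele count) arrays.

    Missing genotypes reduce the called-allele count; alt <= called <= 2 x
    cohort size at every site.
    """
    unknown = [
        sid for ids in part.cohorts.values() for sid in ids if sid not in gm.samples
    ]
    if unknown:
        raise KeyError(f"partition sample ids absent from genotypes: {unknown}")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, ids in part.items():
        cols = gm.sample_columns(ids)
        g = gm.genotypes[:, cols, :]
        called = (g != MISSING).sum(axis=(1, 2))
        alt = (g == 1).sum(axis=(1, 2))
        out[name] = (alt.astype(np.int64), called.astype(np.int64))
    return out
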