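"""Synthetic phased haplotypes, structured populations, sweeps and bioassay counts.

Every generator is deterministic given a seed and produces data with known
ground truth, so each downstream statistic has a parameter-recovery test:

* :func:`simulate_coalescent_window` — neutral Kingman coalescent with
  infinite-sites mutation (no recombination within a window; windows are
  independent), the null model for pi, Watterson's theta, Tajima's D and the
  H12 baseline.
* :func:`inject_sweep` — hard-sweep emulation by haplotype copying: a fraction
  *f* of columns is replaced by one core haplotype, then mutated at rate
  epsilon per copied allele. H12's signal depends only on the resulting
  haplotype-frequency spectrum, so forward simulation of selection is not
  needed.
* :func:`simulate_demes` — Balding–Nichols structured populations whose
  differentiation parameter F equals the expected Hudson F_ST.
* :func:`simulate_bioassay` — binomial mortality counts under a logit-linear
  model, ground truth for the bioassay GLM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from vectorpop.io import (
    MISSING,
    CohortPartition,
    GenotypeMatrix,
    HaplotypeMatrix,
    VariantTable,
)


@dataclass
class NeutralWindowSpec:
    """Neutral coalescent window: 2N haplotypes, scaled mutation rate theta."""

    n_haplotypes: int
    theta: float
    seed: int
    span: tuple[int, int] = (0, 100_000)  # 0-based half-open bp span for positions
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.n_haplotypes < 2:
            raise ValueError("need at least 2 haplotypes")
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even (diploid samples)")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")


@dataclass
class SweepSpec:
    """Hard sweep: fraction f of haplotypes copied from one core, mutated at rate eps."""

    sweep_fraction: float
    residual_mut: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sweep_fraction <= 1.0:
            raise ValueError(f"sweep_fraction must be in [0, 1], got {self.sweep_fraction}")
        if not 0.0 <= self.residual_mut < 1.0:
            raise ValueError("residual_mut must be in [0, 1)")


@dataclass
class DemeSpec:
    """Balding–Nichols demes: per-deme allele frequencies Beta-distributed around p.

    Ancestral frequency p per SNP is drawn Uniform(0.05, 0.95) by default,
    avoiding Beta degeneracy at extreme p; each deme's frequency is
    Beta(p(1-F)/F, (1-p)(1-F)/F) so that E[F_ST] = F.
    """

    deme_sizes: Sequence[int]  # diploids per deme
    F: float
    n_snps: int
    seed: int
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    span: tuple[int, int] = (0, 5_000_000)
    chrom: str = "1"
    deme_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.F < 1.0:
            raise ValueError("F must be in (0, 1)")
        if any(n < 2 for n in self.deme_sizes):
            raise ValueError("each deme needs >= 2 diploids")
        if self.deme_names is None:
            self.deme_names = [f"deme{i}" for i in range(len(self.deme_sizes))]


@dataclass
class BioassaySimSpec:
    """Binomial tube-bioassay design under a logit-linear mortality model.

    Mortality in cell (site s, insecticide i) is
    inverse-logit(intercept + site_effects[s] + insecticide_effects[i]);
    the control arm is Binomial(control_n, control_mortality).
    """

    sites: Sequence[str]
    insecticides: Sequence[str]
    intercept: float
    site_effects: dict[str, float] = field(default_factory=dict)
    insecticide_effects: dict[str, float] = field(default_factory=dict)
    n_exposed: int = 100
    control_n: int = 25
    control_mortality: float = 0.02

    def __post_init__(self) -> None:
        if self.n_exposed < 1 or self.control_n < 1:
            raise ValueError("exposed counts must be >= 1")
        if not 0.0 < self.control_mortality < 1.0:
            raise ValueError("control mortality must be in (0, 1)")

    def cell_probability(self, site: str, insecticide: str) -> float:
        eta = (
            self.intercept
            + self.site_effects.get(site, 0.0)
            + self.insecticide_effects.get(insecticide, 0.0)
        )
        return 1.0 / (1.0 + np.exp(-eta))


def _draw_positions(rng: np.random.Generator, n: int, span: tuple[int, int]) -> np.ndarray:
    lo, hi = span
    if hi - lo < n:
        raise ValueError(f"span {span} too small for {n} distinct positions")
    pos = rng.choice(hi - lo, size=n, replace=False) + lo
    pos.sort()
    return pos.astype(np.int64)


def _hap_matrix(
    alleles: np.ndarray, rng: np.random.Generator, span: tuple[int, int], chrom: str,
    samples: list[str] | None = None,
) -> HaplotypeMatrix:
    n_sites, n_hap = alleles.shape
    pos0 = _draw_positions(rng, n_sites, span)
    variants = VariantTable(
        np.full(n_sites, chrom, dtype=object),
        pos0,
        np.full(n_sites, "A", dtype=object),
        np.full(n_sites, "T", dtype=object),
    )
    if samples is None:
        samples = [f"sim{i:04d}" for i in range(n_hap // 2)]
    return HaplotypeMatrix(alleles.astype(np.int8), samples, variants)


def simulate_coalescent_window(spec: NeutralWindowSpec) -> HaplotypeMatrix:
    """Neutral Kingman coalescent window with infinite-sites mutation.

    While k lineages remain, an exponential waiting time with rate k(k-1)/2
    elapses and a uniformly chosen pair merges. Mutations fall as a Poisson
    process with rate theta/2 per unit branch length; each mutation creates a
    new biallelic site whose derived allele is carried by the leaves below the
    mutated branch. Sites are returned sorted by an assigned position.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_haplotypes
    # active lineages: (leaf index array, accrued branch length)
    active: list[tuple[np.ndarray, float]] = [
        (np.array([i]), 0.0) for i in range(n)
    ]
    edges: list[tuple[np.ndarray, float]] = []
    k = n
    while k > 1:
        t = rng.exponential(2.0 / (k * (k - 1)))
        active = [(leaves, length + t) for leaves, length in active]
        i, j = sorted(int(x) for x in rng.choice(k, size=2, replace=False))
        merged = np.concatenate([active[i][0], active[j][0]])
        edges.append(active[j])
        edges.append(active[i])
        del active[j]
        del active[i]
        active.append((merged, 0.0))
        k -= 1
    # the root lineage accrues no further time and carries no mutations

    lengths = np.array([length for _, length in edges])
    total = lengths.sum()
    n_mut = rng.poisson(spec.theta / 2.0 * total)
    if n_mut == 0:
        alleles = np.empty((0, n), dtype=np.int8)
    else:
        which = rng.choice(len(edges), size=n_mut, p=lengths / total)
        alleles = np.zeros((n_mut, n), dtype=np.int8)
        for row, e in enumerate(which):
            alleles[row, edges[e][0]] = 1
    return _hap_matrix(alleles, rng, spec.span, spec.chrom)


def inject_sweep(hm: HaplotypeMatrix, spec: SweepSpec, seed: int) -> HaplotypeMatrix:
    """Replace round(f * 2N) random columns with copies of one core haplotype.

    Each copied allele then flips independently with probability
    ``spec.residual_mut``, emulating mutation accumulated since the sweep.
    Dimensions and site positions are unchanged; ``f = 0`` returns a copy of
    the input.
    """
    rng = np.random.default_rng(seed)
    alleles = hm.alleles.copy()
    n_hap = alleles.shape[1]
    n_swept = int(round(spec.sweep_fraction * n_hap))
    if n_swept > 0:
        core = int(rng.integers(n_hap))
        targets = rng.choice(n_hap, size=n_swept, replace=False)
        alleles[:, targets] = alleles[:, [core]]
        if spec.residual_mut > 0 and alleles.size:
            flips = rng.random((alleles.shape[0], n_swept)) < spec.residual_mut
            block = alleles[:, targets]
            block[flips] = 1 - block[flips]
            alleles[:, targets] = block
    return HaplotypeMatrix(alleles, hm.samples, hm.variants, hm.site_index)


def simulate_demes(
    spec: DemeSpec,
) -> tuple[GenotypeMatrix, HaplotypeMatrix, CohortPartition]:
    """Balding–Nichols structured genotypes with E[F_ST] = F.

    Per SNP an ancestral frequency p ~ Uniform(ancestral_low, ancestral_high)
    is drawn; each deme's frequency q_d ~ Beta(p(1-F)/F, (1-p)(1-F)/F); each
    haplotype allele ~ Bernoulli(q_d). Diploids pair adjacent haplotypes.
    """
    rng = np.random.default_rng(spec.seed)
    S = spec.n_snps
    F = spec.F
    p = rng.uniform(spec.ancestral_low, spec.ancestral_high, size=S)
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F

    hap_blocks: list[np.ndarray] = []
    samples: list[str] = []
    cohorts: dict[str, list[str]] = {}
    for d, (name, size) in enumerate(zip(spec.deme_names, spec.deme_sizes)):
        q = rng.beta(a, b)
        block = (rng.random((S, 2 * size)) < q[:, None]).astype(np.int8)
        hap_blocks.append(block)
        ids = [f"{name}_{i:03d}" for i in range(size)]
        samples.extend(ids)
        cohorts[name] = ids

    alleles = np.hstack(hap_blocks)
    hm = _hap_matrix(alleles, rng, spec.span, spec.chrom, samples=samples)
    gm = GenotypeMatrix(
        alleles.reshape(S, len(samples), 2), samples, hm.variants
    )
    return gm, hm, CohortPartition(cohorts)


def simulate_bioassay(spec: BioassaySimSpec, seed: int) -> list:
    """Binomial dead counts per site x insecticide cell, plus control arms."""
    from vectorpop.bioassay import BioassayRecord

    rng = np.random.default_rng(seed)
    records = []
    for site in spec.sites:
        for ins in spec.insecticides:
            pr = spec.cell_probability(site, ins)
            dead = int(rng.binomial(spec.n_exposed, pr))
            ctrl_dead = int(rng.binomial(spec.control_n, spec.control_mortality))
            records.append(
                BioassayRecord(
                    site=site,
                    subsite=site,
                    insecticide=ins,
                    n_exposed=spec.n_exposed,
                    n_dead=dead,
                    control_n=spec.control_n,
                    control_dead=ctrl_dead,
                )
            )
    return records


def concat_windows(windows: Sequence[HaplotypeMatrix], gap: int = 0) -> HaplotypeMatrix:
    """Stack independent windows into one chromosome, offsetting positions.

    Each window's positions are shifted so windows are laid end to end
    (plus ``gap`` bp between them); sample ids come from the first window.
    """
    if not windows:
        raise ValueError("no windows to concatenate")
    n_hap = windows[0].n_haplotypes
    if any(w.n_haplotypes != n_hap for w in windows):
        raise ValueError("windows must share the haplotype dimension")
    alleles = np.vstack([w.alleles for w in windows])
    pos_parts = []
    offset = 0
    for w in windows:
        pos_parts.append(w.variants.pos0 + offset)
        span_len = int(w.variants.pos0[-1]) + 1 if w.n_sites else 0
        offset += span_len + gap
    pos0 = np.concatenate(pos_parts)
    chrom = windows[0].variants.chrom[0] if windows[0].n_sites else "1"
    variants = VariantTable(
        np.full(len(pos0), chrom, dtype=object),
        pos0,
        np.full(len(pos0), "A", dtype=object),
        np.full(len(pos0), "T", dtype=object),
    )
    return HaplotypeMatrix(alleles, windows[0].samples, variants)


def genotypes_from_haplotypes(hm: HaplotypeMatrix) -> GenotypeMatrix:
    """Pair adjacent haplotype columns into diploid genotypes (fully phased)."""
    S, n_hap = hm.alleles.shape
    return GenotypeMatrix(hm.alleles.reshape(S, n_hap // 2, 2), hm.samples, hm.variants)


def write_fixture(
    vcf_path: str | Path,
    gm: GenotypeMatrix,
    phased_mask: np.ndarray | None = None,
    metadata_path: str | Path | None = None,
    metadata_rows: Sequence[dict] | None = None,
) -> Path:
    """Write genotypes as a VCF 4.2 fixture parseable by ``read_phased_vcf``.

    ``phased_mask`` marks sites written with ``|`` separators (default: all).
    When ``metadata_path`` is given, a matching sample-metadata TSV is written
    from ``metadata_rows`` (default: every sample in one cohort with passing
    coverage).
    """
    vcf_path = Path(vcf_path)
    vcf_path.parent.mkdir(parents=True, exist_ok=True)
    S = gm.n_sites
    if phased_mask is None:
        phased_mask = np.ones(S, dtype=bool)

    lines = ["##fileformat=VCFv4.2", "##source=vectorpop-synthetic"]
    for chrom in dict.fromkeys(gm.variants.chrom):  # preserve order, unique
        mask = gm.variants.chrom == chrom
        length = int(gm.variants.pos0[mask].max()) + 2 if mask.any() else 1
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples)
    )
    for s in range(S):
        sep = "|" if phased_mask[s] else "/"
        gts = []
        for j in range(gm.n_samples):
            a, b = gm.genotypes[s, j]
            aa = "." if a == MISSING else str(int(a))
            bb = "." if b == MISSING else str(int(b))
            gts.append(f"{aa}{sep}{bb}")
        lines.append(
            "\t".join(
                [
                    str(gm.variants.chrom[s]),
                    str(int(gm.variants.pos1[s])),
                    ".",
                    str(gm.variants.ref[s]),
                    str(gm.variants.alt[s]),
                    ".",
                    "PASS",
                    ".",
                    "GT",
                ]
                + gts
            )
        )
    vcf_path.write_text("\n".join(lines) + "\n")

    if metadata_path is not None:
        import pandas as pd

        if metadata_rows is None:
            metadata_rows = [
                {
                    "sample_id": sid,
                    "site": "simsite",
                    "subsite": "simsub",
                    "cohort": "sim",
                    "mean_coverage": 30.0,
                    "x_3r_ratio": 1.0,
                }
                for sid in gm.samples
            ]
        pd.DataFrame(metadata_rows).to_csv(metadata_path, sep="\t", index=False)
    return vcf_path
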