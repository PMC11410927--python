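import numpy as np
import pytest

from vectorpop.io import HaplotypeMatrix, VariantTable
from vectorpop.simulate import DemeSpec, simulate_demes


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_window(alleles: np.ndarray, chrom: str = "1") -> HaplotypeMatrix:
    """Wrap a (sites x haplotypes) 0/1 array as a HaplotypeMatrix with unit-spaced positions."""
    alleles = np.asarray(alleles, dtype=np.int8)
    S, n_hap = alleles.shape
    variants = VariantTable(
        np.full(S, chrom, dtype=object),
        np.arange(S, dtype=np.int64) * 10,
        np.full(S, "A", dtype=object),
        np.full(S, "T", dtype=object),
    )
    samples = [f"s{i}" for i in range(n_hap // 2)]
    return HaplotypeMatrix(alleles, samples, variants)


def random_window(rng: np.random.Generator, n_sites: int, n_hap: int) -> HaplotypeMatrix:
    return make_window(rng.integers(0, 2, size=(n_sites, n_hap)))


def iid_block(n_hap: int, n_snps: int, seed: int, chrom: str = "1") -> HaplotypeMatrix:
    """LD-free haplotype block: per-site frequencies drawn around Uniform(0.05, 0.95)."""
    spec = DemeSpec(
        [n_hap // 2], F=0.5, n_snps=n_snps, seed=seed, span=(0, 200_000), chrom=chrom
    )
    _, hm, _ = simulate_demes(spec)
    return hm
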