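"""End-to-end orchestration: QC -> cohorts -> diversity, H12, F_ST, PCA, markers, bioassay.

A run is driven by a single YAML config with explicit seeds; every output TSV
carries a comment header echoing the parameters, and a manifest maps each
output file to its SHA-256 checksum so that identical configs and inputs
reproduce identical manifests.

:func:`make_demo` writes a complete synthetic fixture bundle emulating the
study design — four analysis cohorts over Balding–Nichols background
structure, one cohort carrying an injected sweep and a fixed gene
amplification, marker sites with known cohort frequencies, and simulated
bioassays in which that cohort is the most resistant — together with a
ground-truth JSON for recovery checks.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from vectorpop import io as vio
from vectorpop import simulate as sim
from vectorpop._util import sha256_of, write_tsv
from vectorpop.bioassay import fit_binomial_glm, read_bioassay_tsv, summarize_bioassay
from vectorpop.diversity import cohort_diversity_summary
from vectorpop.fst import fst_scan
from vectorpop.markers import cnv_frequencies, load_marker_panel, marker_frequencies, read_cnv_calls
from vectorpop.pca import pca_per_arm
from vectorpop.selection import call_peaks, h_scan


@dataclass
class RunConfig:
    vcf: str
    metadata: str
    outdir: str
    panel: str | None = None
    cnv_calls: str | None = None
    bioassay: str | None = None
    min_coverage: float = 10.0
    h12_window: int = 1000
    h12_step: int | None = None
    fst_window: int = 1000
    fst_step: int | None = 500
    diversity_window: int = 1000
    peak_threshold: float = 0.1
    peak_min_contiguous: int = 2
    maf_min: float = 0.01
    max_missing: float = 0.1
    n_components: int = 6
    fst_pairs: list[tuple[str, str]] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for attr in ("vcf", "metadata", "panel", "cnv_calls", "bioassay"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {attr} path does not exist: {p}")
        if self.min_coverage <= 0:
            raise ValueError("min_coverage must be > 0")
        for name in ("h12_window", "fst_window", "diversity_window"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.fst_pairs is not None:
            self.fst_pairs = [tuple(p) for p in self.fst_pairs]


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run every configured stage in dependency order; return the output manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def record(path: Path) -> None:
        manifest[path.name] = sha256_of(path)

    # --- QC and cohorts -----------------------------------------------------
    samples = vio.read_sample_metadata(config.metadata)
    passed = [
        s for s in vio.qc_filter_samples(samples, config.min_coverage)
        if s.sex != "excluded"
    ]
    qc_df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "cohort": s.cohort,
                "mean_coverage": s.mean_coverage,
                "x_3r_ratio": s.x_3r_ratio,
                "sex": s.sex,
                "passed_qc": s in passed,
            }
            for s in samples
        ]
    )
    record(write_tsv(qc_df, outdir / "sample_qc.tsv", {"min_coverage": config.min_coverage}))
    if not passed:
        raise RuntimeError("stage qc: no samples pass QC")
    part = vio.CohortPartition.from_samples(passed)

    variants, hm_all, gm_all = vio.read_phased_vcf(config.vcf)
    keep_ids = [s.sample_id for s in passed if s.sample_id in gm_all.samples]
    cols = gm_all.sample_columns(keep_ids)
    gm = vio.GenotypeMatrix(gm_all.genotypes[:, cols, :], keep_ids, gm_all.variants)
    hm_cols = np.concatenate([[2 * c, 2 * c + 1] for c in cols]) if len(cols) else np.empty(0, int)
    hm = vio.HaplotypeMatrix(hm_all.alleles[:, hm_cols], keep_ids, hm_all.variants, hm_all.site_index)
    part = vio.CohortPartition(
        {k: [s for s in ids if s in keep_ids] for k, ids in part.items() if any(s in keep_ids for s in ids)}
    )

    # --- diversity ----------------------------------------------------------
    div = cohort_diversity_summary(hm, part, window_size_snps=config.diversity_window)
    div_df = pd.DataFrame([dataclasses.asdict(r) for r in div])
    record(write_tsv(div_df, outdir / "diversity.tsv", {"window_snps": config.diversity_window}))

    # --- H12 scan + peaks ---------------------------------------------------
    h_rows, peak_rows = [], []
    for cohort, ids in part.items():
        sub = hm.subset_samples(ids)
        for chrom in dict.fromkeys(sub.variants.chrom):
            idx = np.flatnonzero(sub.variants.chrom == chrom)
            if len(idx) < config.h12_window / 2:
                continue  # marker-only arms carry too few SNPs to scan
            sub_c = vio.HaplotypeMatrix(sub.alleles[idx], sub.samples, sub.variants.take(idx))
            res = h_scan(sub_c, config.h12_window, config.h12_step, cohort=cohort)
            h_rows.extend(dataclasses.asdict(r) for r in res)
            for p in call_peaks(res, config.peak_threshold, config.peak_min_contiguous):
                peak_rows.append({"cohort": cohort, **dataclasses.asdict(p)})
    record(write_tsv(pd.DataFrame(h_rows), outdir / "h12_scan.tsv",
                     {"window_snps": config.h12_window, "step": config.h12_step}))
    record(write_tsv(pd.DataFrame(peak_rows), outdir / "h12_peaks.tsv",
                     {"threshold": config.peak_threshold,
                      "min_contiguous": config.peak_min_contiguous}))
    bed = pd.DataFrame(
        [
            {"chrom": p["chrom"], "start": p["start"] - 1, "end": p["end"],
             "name": f"{p['cohort']}_h12_peak"}
            for p in peak_rows
        ]
    )
    bed_path = outdir / "h12_peaks.bed"
    bed.to_csv(bed_path, sep="\t", index=False, header=False, lineterminator="\n")
    record(bed_path)

    # --- F_ST scan ----------------------------------------------------------
    pairs = config.fst_pairs
    if pairs is None:
        names = part.names
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    fst_rows = []
    for pair in pairs:
        for chrom in dict.fromkeys(gm.variants.chrom):
            idx = np.flatnonzero(gm.variants.chrom == chrom)
            sub_gm = vio.GenotypeMatrix(gm.genotypes[idx], gm.samples, gm.variants.take(idx))
            for r in fst_scan(sub_gm, part, tuple(pair), config.fst_window, config.fst_step):
                d = dataclasses.asdict(r)
                d["pop1"], d["pop2"] = d.pop("cohort_pair")
                fst_rows.append(d)
    record(write_tsv(pd.DataFrame(fst_rows), outdir / "fst_scan.tsv",
                     {"window_snps": config.fst_window, "step": config.fst_step}))

    # --- PCA per chromosome arm --------------------------------------------
    pca_rows, var_rows = [], []
    for chrom, res in pca_per_arm(gm, config.n_components, config.maf_min, config.max_missing).items():
        for i, sid in enumerate(res.sample_ids):
            row = {"chrom": chrom, "sample_id": sid}
            for c in range(res.coordinates.shape[1]):
                row[f"PC{c + 1}"] = res.coordinates[i, c]
            pca_rows.append(row)
        for c, v in enumerate(res.explained_variance_ratio):
            var_rows.append({"chrom": chrom, "component": c + 1, "explained_variance_ratio": v})
    record(write_tsv(pd.DataFrame(pca_rows), outdir / "pca_coordinates.tsv",
                     {"maf_min": config.maf_min, "max_missing": config.max_missing}))
    record(write_tsv(pd.DataFrame(var_rows), outdir / "pca_variance.tsv", {}))

    # --- marker and CNV frequencies ----------------------------------------
    panel = load_marker_panel(config.panel)
    rows = marker_frequencies(gm, gm.variants, part, panel)
    record(write_tsv(pd.DataFrame([dataclasses.asdict(r) for r in rows]),
                     outdir / "marker_frequencies.tsv", {"panel": config.panel or "bundled"}))
    if config.cnv_calls:
        cnv_rows = cnv_frequencies(read_cnv_calls(config.cnv_calls), part)
        record(write_tsv(pd.DataFrame([dataclasses.asdict(r) for r in cnv_rows]),
                         outdir / "cnv_frequencies.tsv", {}))

    # --- bioassay -----------------------------------------------------------
    if config.bioassay:
        recs = read_bioassay_tsv(config.bioassay)
        summ = summarize_bioassay(recs)
        record(write_tsv(pd.DataFrame([dataclasses.asdict(s) for s in summ]),
                         outdir / "bioassay_summary.tsv", {}))
        fit = fit_binomial_glm(recs)
        glm_df = pd.DataFrame(
            [
                {"term": t, "wald_chi2": fit.wald_chi2[t], "df": fit.df[t],
                 "p_value": fit.p_values[t]}
                for t in fit.wald_chi2
            ]
        )
        record(write_tsv(glm_df, outdir / "bioassay_glm.tsv",
                         {"converged": fit.converged, "deviance": round(fit.deviance, 6)}))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# demo fixture bundle

DEMO_COHORTS = ["Kimpese_Kilueka", "Kimpese_Yanga", "Kapolowe", "Mikalayi"]


def make_demo(
    outdir: str | Path,
    seed: int = 0,
    n_per_cohort: int = 20,
    n_blocks: int = 10,
    snps_per_block: int = 120,
    background_f: float = 0.05,
    sweep_block: int = 4,
    sweep_fraction: float = 0.6,
    sweep_cohort: str = "Kimpese_Kilueka",
) -> dict:
    """Write a synthetic fixture bundle emulating the four-cohort study design.

    The chromosome is ``n_blocks`` independent Balding–Nichols blocks
    (4 demes, F = ``background_f``); inside ``sweep_block`` the
    ``sweep_cohort`` haplotypes receive an injected hard sweep
    (f = ``sweep_fraction``). Marker sites with fixed per-cohort frequencies,
    a CNV fixed in the two Kimpese cohorts, and bioassay counts in which
    Kimpese is the most resistant site complete the bundle. Ground truth is
    written to ``ground_truth.json``.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    block_span = 200_000

    blocks = []
    for b in range(n_blocks):
        spec = sim.DemeSpec(
            deme_sizes=[n_per_cohort] * 4,
            F=background_f,
            n_snps=snps_per_block,
            seed=int(rng.integers(2**31)),
            span=(0, block_span),
            chrom="2R",
            deme_names=DEMO_COHORTS,
        )
        _, hm_b, part = sim.simulate_demes(spec)
        blocks.append(hm_b)

    # inject the sweep into the sweep cohort's haplotype columns of one block
    sweep_ids = part[sweep_cohort]
    hm_sw = blocks[sweep_block]
    sub = hm_sw.subset_samples(sweep_ids)
    # residual mutation scaled so eps * block SNPs << 1 (recent sweep: copies near-identical)
    swept = sim.inject_sweep(
        sub, sim.SweepSpec(sweep_fraction, residual_mut=0.001), seed=int(rng.integers(2**31))
    )
    col_idx = []
    for sid in sweep_ids:
        j = hm_sw.samples.index(sid)
        col_idx.extend([2 * j, 2 * j + 1])
    hm_sw.alleles[:, col_idx] = swept.alleles

    chrom_hm = sim.concat_windows(blocks)
    sweep_start = int(chrom_hm.variants.pos1[sweep_block * snps_per_block])
    sweep_end = int(chrom_hm.variants.pos1[(sweep_block + 1) * snps_per_block - 1])

    gm = sim.genotypes_from_haplotypes(chrom_hm)

    # marker sites on their own arms with known per-cohort frequencies
    panel = load_marker_panel()
    marker_truth: dict[str, dict[str, float]] = {}
    marker_sites = []
    # (offset within codon, coding-strand ref/alt) realising each substitution
    changes = {"L995F": (2, "A", "T"), "K75N": (2, "A", "T"), "T319N": (1, "C", "A")}
    use = [m for m in panel if m.label in changes]
    for mdef in use:
        if mdef.label == "L995F":  # kdr: high everywhere, as in field populations
            freqs = {c: 0.9 for c in DEMO_COHORTS}
        else:
            freqs = {c: float(rng.choice([0.0, 0.1, 0.3, 0.5, 0.7, 0.9])) for c in DEMO_COHORTS}
        marker_truth[mdef.label] = freqs
        offset, ref_coding, alt_coding = changes[mdef.label]
        pos1 = mdef.codon_positions[offset]
        genotypes = np.zeros((1, gm.n_samples, 2), dtype=np.int8)
        for cohort, ids in part.items():
            p = freqs[cohort]
            for sid in ids:
                j = gm.samples.index(sid)
                genotypes[0, j] = rng.random(2) < p
        marker_sites.append(
            {
                "chrom": mdef.chrom, "pos1": pos1, "ref": ref_coding, "alt": alt_coding,
                "strand": mdef.strand, "genotypes": genotypes,
            }
        )

    # assemble a combined genotype matrix: 2R scan sites + marker sites on other arms
    all_chrom = list(gm.variants.chrom) + [m["chrom"] for m in marker_sites]
    all_pos0 = list(gm.variants.pos0) + [m["pos1"] - 1 for m in marker_sites]
    all_ref = list(gm.variants.ref) + [m["ref"] for m in marker_sites]
    all_alt = list(gm.variants.alt) + [m["alt"] for m in marker_sites]
    order = np.lexsort((np.array(all_pos0), np.array(all_chrom, dtype=object)))
    variants = vio.VariantTable(
        np.array(all_chrom, dtype=object)[order],
        np.array(all_pos0)[order],
        np.array(all_ref, dtype=object)[order],
        np.array(all_alt, dtype=object)[order],
    )
    geno = np.concatenate([gm.genotypes] + [m["genotypes"] for m in marker_sites], axis=0)[order]
    gm_full = vio.GenotypeMatrix(geno, gm.samples, variants)

    vcf_path = outdir / "demo.vcf"
    meta_path = outdir / "metadata.tsv"
    metadata_rows = []
    for cohort, ids in part.items():
        site = cohort.split("_")[0]
        for sid in ids:
            metadata_rows.append(
                {
                    "sample_id": sid, "site": site, "subsite": cohort, "cohort": cohort,
                    "mean_coverage": float(np.round(rng.uniform(15, 40), 1)),
                    "x_3r_ratio": float(np.round(rng.uniform(0.85, 1.15), 2)),
                }
            )
    sim.write_fixture(vcf_path, gm_full, metadata_path=meta_path, metadata_rows=metadata_rows)

    # CNV calls: Cyp9k1 amplification fixed in both Kimpese cohorts, absent elsewhere
    cnv_rows = []
    for cohort, ids in part.items():
        amplified = cohort.startswith("Kimpese")
        for sid in ids:
            cnv_rows.append(
                {"sample_id": sid, "gene_region": "Cyp9k1",
                 "copy_number": 4 if amplified else 2}
            )
    cnv_path = outdir / "cnv_calls.tsv"
    pd.DataFrame(cnv_rows).to_csv(cnv_path, sep="\t", index=False, lineterminator="\n")

    # bioassay: Kimpese most resistant (lowest mortality), Mikalayi least
    site_effects = {"Kimpese": -1.6, "Kapolowe": -0.4, "Mikalayi": 0.9}
    bspec = sim.BioassaySimSpec(
        sites=["Kimpese", "Kapolowe", "Mikalayi"],
        insecticides=["alpha-cypermethrin 0.05%", "deltamethrin 0.05%", "permethrin 0.75%"],
        intercept=1.2,
        site_effects=site_effects,
        insecticide_effects={"deltamethrin 0.05%": -0.5},
        n_exposed=100,
    )
    brecords = sim.simulate_bioassay(bspec, seed=int(rng.integers(2**31)))
    bio_path = outdir / "bioassay.tsv"
    pd.DataFrame([dataclasses.asdict(r) for r in brecords]).to_csv(
        bio_path, sep="\t", index=False, lineterminator="\n"
    )

    truth = {
        "seed": seed,
        "sweep": {
            "cohort": sweep_cohort, "chrom": "2R",
            "start": sweep_start, "end": sweep_end,
            "fraction": sweep_fraction,
        },
        "background_f": background_f,
        "fixed_cnv": {"gene_region": "Cyp9k1",
                      "cohorts": [c for c in DEMO_COHORTS if c.startswith("Kimpese")]},
        "marker_frequencies": marker_truth,
        "bioassay": {"intercept": bspec.intercept, "site_effects": site_effects,
                     "most_resistant_site": "Kimpese"},
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)

    config = RunConfig(
        vcf=str(vcf_path),
        metadata=str(meta_path),
        outdir=str(outdir / "results"),
        cnv_calls=str(cnv_path),
        bioassay=str(bio_path),
        h12_window=snps_per_block,
        h12_step=None,
        fst_window=snps_per_block,
        fst_step=snps_per_block,
        diversity_window=snps_per_block,
        peak_min_contiguous=1,
        fst_pairs=[("Kimpese_Kilueka", "Mikalayi")],
        seed=seed,
    )
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return truth
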