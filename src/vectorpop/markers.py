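"""Resistance-marker SNP and CNV frequency tabulation.

The marker panel is codon-level: each entry names a gene, a codon number, the
three genomic coordinates of the codon in transcription order and the
reference codon on the coding strand (e.g. Vgsc L995F, the classic kdr
pyrethroid target-site mutation). VCF variants at panel positions are
translated into amino-acid substitution labels; cohort frequencies are alt
alleles over called alleles. CNV calls (integer copy number per sample and
gene region, diploid baseline 2) are summarised as carrier proportion
(copy number > 2) or mean copy number, with a "fixed" flag at carrier
proportion 1 — the pattern reported for Cyp9k1 amplification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from vectorpop.io import MISSING, CohortPartition, GenotypeMatrix, VariantTable


def _translate(codon: str) -> str:
    codon = codon.upper()
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


@dataclass
class MarkerDef:
    """Codon-level definition of a resistance locus, e.g. label "L995F"."""

    gene: str
    label: str
    chrom: str
    strand: str  # '+' or '-'
    codon_number: int
    codon_positions: tuple[int, int, int]  # 1-based genomic, transcription order
    ref_codon: str  # coding strand

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.codon_positions) != 3:
            raise ValueError("a codon has exactly 3 positions")
        if len(self.ref_codon) != 3:
            raise ValueError("ref_codon must be 3 bases")
        ref_aa = _translate(self.ref_codon)
        if not self.label.startswith(f"{ref_aa}{self.codon_number}"):
            raise ValueError(
                f"ref_codon {self.ref_codon} translates to {ref_aa}, inconsistent with"
                f" label {self.label!r} at codon {self.codon_number}"
            )

    @property
    def ref_aa(self) -> str:
        return _translate(self.ref_codon)

    @property
    def alt_aa(self) -> str:
        return self.label[len(f"{self.ref_aa}{self.codon_number}"):]


@dataclass
class CnvCall:
    sample_id: str
    gene_region: str
    copy_number: int

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")


@dataclass
class MarkerFrequencyRow:
    cohort: str
    gene: str
    label: str
    alt_count: int
    called_alleles: int
    frequency: float
    site_absent: bool = False


@dataclass
class CnvFrequencyRow:
    cohort: str
    gene_region: str
    n_samples: int
    carrier_proportion: float
    mean_copy_number: float
    fixed: bool


def annotate_aa_change(mdef: MarkerDef, pos: int, ref: str, alt: str) -> str:
    """Amino-acid substitution label for a SNP inside the marker's codon.

    On '-' strand genes the VCF ref/alt are reverse-complemented into coding
    orientation before substitution; identical amino acids return
    "synonymous".
    """
    if pos not in mdef.codon_positions:
        raise ValueError(f"position {pos} not in codon of {mdef.gene} {mdef.label}")
    offset = mdef.codon_positions.index(pos)
    if mdef.strand == "-":
        ref = str(Seq(ref).reverse_complement())
        alt = str(Seq(alt).reverse_complement())
    if mdef.ref_codon[offset].upper() != ref.upper():
        raise ValueError(
            f"variant ref {ref!r} inconsistent with codon base"
            f" {mdef.ref_codon[offset]!r} at offset {offset} of {mdef.gene} {mdef.label}"
        )
    alt_codon = mdef.ref_codon[:offset] + alt.upper() + mdef.ref_codon[offset + 1:]
    ref_aa, alt_aa = _translate(mdef.ref_codon), _translate(alt_codon)
    if ref_aa == alt_aa:
        return "synonymous"
    return f"{ref_aa}{mdef.codon_number}{alt_aa}"


def marker_frequencies(
    gm: GenotypeMatrix,
    variants: VariantTable,
    part: CohortPartition,
    panel: Sequence[MarkerDef],
) -> list[MarkerFrequencyRow]:
    """Cohort frequency of each panel marker; absent sites reported at 0.

    A marker's site is the variant at one of its codon positions whose
    annotated substitution equals the marker label. Rows are emitted for every
    cohort x marker even when the mutation is absent from the data, matching
    surveillance-table conventions.
    """
    from vectorpop.io import allele_counts_by_cohort

    counts = allele_counts_by_cohort(gm, part)
    rows: list[MarkerFrequencyRow] = []
    for mdef in panel:
        site = None
        for s in range(variants.n_sites):
            if (
                variants.chrom[s] == mdef.chrom
                and int(variants.pos1[s]) in mdef.codon_positions
            ):
                label = annotate_aa_change(
                    mdef, int(variants.pos1[s]), str(variants.ref[s]), str(variants.alt[s])
                )
                if label == mdef.label:
                    site = s
                    break
        for cohort, ids in part.items():
            if site is None:
                rows.append(
                    MarkerFrequencyRow(cohort, mdef.gene, mdef.label, 0, 0, 0.0, True)
                )
            else:
                alt, called = counts[cohort]
                a, c = int(alt[site]), int(called[site])
                rows.append(
                    MarkerFrequencyRow(
                        cohort, mdef.gene, mdef.label, a, c, a / c if c else math.nan
                    )
                )
    return rows


def cnv_frequencies(
    calls: Sequence[CnvCall],
    part: CohortPartition,
    mode: str = "carrier",
) -> list[CnvFrequencyRow]:
    """Per-cohort CNV summary: carrier proportion (copy > 2) and mean copy number.

    ``mode`` selects which value downstream tables call "frequency"; both are
    always computed. Duplicate (sample, region) calls are an error; a cohort
    with no calls for a region yields n = 0 with NaN frequencies.
    """
    if mode not in ("carrier", "mean_copy"):
        raise ValueError("mode must be 'carrier' or 'mean_copy'")
    seen: set[tuple[str, str]] = set()
    by_region: dict[str, dict[str, int]] = {}
    for call in calls:
        key = (call.sample_id, call.gene_region)
        if key in seen:
            raise ValueError(f"duplicate CNV call for {key}")
        seen.add(key)
        by_region.setdefault(call.gene_region, {})[call.sample_id] = call.copy_number
    rows: list[CnvFrequencyRow] = []
    for region, copy_of in by_region.items():
        for cohort, ids in part.items():
            copies = [copy_of[s] for s in ids if s in copy_of]
            n = len(copies)
            if n == 0:
                rows.append(CnvFrequencyRow(cohort, region, 0, math.nan, math.nan, False))
                continue
            carrier = sum(c > 2 for c in copies) / n
            rows.append(
                CnvFrequencyRow(
                    cohort, region, n, carrier, float(np.mean(copies)), carrier == 1.0
                )
            )
    return rows


def load_marker_panel(path: str | Path | None = None) -> list[MarkerDef]:
    """Read a marker-panel TSV (gene, label, chrom, strand, codon_number, pos1..3, ref_codon).

    Without a path, the bundled synthetic surveillance panel is loaded: the
    genes and substitutions screened in *An. gambiae* resistance monitoring
    (Vgsc 995F/995S/R254K/N1570Y, Rdl, Ace1, Cyp4j5, Cyp6p4, Cpr) with
    placeholder coordinates for testing against synthetic VCFs.
    """
    if path is None:
        ref = resources.files("vectorpop.data").joinpath("marker_panel_synthetic.tsv")
        with resources.as_file(ref) as p:
            return load_marker_panel(p)
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        MarkerDef(
            gene=row.gene,
            label=row.label,
            chrom=str(row.chrom),
            strand=row.strand,
            codon_number=int(row.codon_number),
            codon_positions=(int(row.pos1), int(row.pos2), int(row.pos3)),
            ref_codon=row.ref_codon,
        )
        for row in df.itertuples()
    ]


def read_cnv_calls(path: str | Path) -> list[CnvCall]:
    """Read CNV calls TSV: sample_id, gene_region, copy_number."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    return [
        CnvCall(row.sample_id, row.gene_region, int(row.copy_number))
        for row in df.itertuples()
    ]
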