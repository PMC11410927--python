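"""Resistance-marker annotation and cohort frequency tables (SNPs and CNVs).

Translates a kdr substitution from its codon definition, then tabulates
per-cohort frequencies for a small genotype fixture and a CNV call set with a
fixed amplification — the surveillance-table building blocks.
"""

import numpy as np

from vectorpop.io import CohortPartition, GenotypeMatrix, VariantTable
from vectorpop.markers import (
    CnvCall,
    annotate_aa_change,
    cnv_frequencies,
    load_marker_panel,
    marker_frequencies,
)

panel = load_marker_panel()
l995f = next(m for m in panel if m.label == "L995F")
label = annotate_aa_change(l995f, l995f.codon_positions[2], "A", "T")
print(f"Vgsc codon 995 TTA with third-position A->T annotates as: {label} (kdr)")

# 10 samples, 4 het + 3 hom-alt at the kdr site -> frequency 0.5
geno = np.array([[[0, 1]] * 4 + [[1, 1]] * 3 + [[0, 0]] * 3], dtype=np.int8)
variants = VariantTable([l995f.chrom], [l995f.codon_positions[2] - 1], ["A"], ["T"])
ids = [f"s{i}" for i in range(10)]
gm = GenotypeMatrix(geno, ids, variants)
rows = marker_frequencies(gm, variants, CohortPartition({"Kimpese": ids}), [l995f])
for r in rows:
    print(f"{r.cohort}: {r.gene} {r.label} frequency = {r.frequency:.2f} "
          f"({r.alt_count}/{r.called_alleles} alleles)")

calls = [CnvCall(s, "Cyp9k1", 4) for s in ids[:5]] + [CnvCall(s, "Cyp9k1", 2) for s in ids[5:]]
for row in cnv_frequencies(calls, CohortPartition({"a": ids[:5], "b": ids[5:]})):
    tag = " (fixed)" if row.fixed else ""
    print(f"cohort {row.cohort}: Cyp9k1 carrier proportion = {row.carrier_proportion:.2f}, "
          f"mean copy = {row.mean_copy_number:.2f}{tag}")
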