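# Methods

This note documents the models, estimators and numerical choices behind
`vectorpop`, and what the synthetic-data tests do and do not establish about
real data.

## Data model and coordinates

All internal coordinates are 0-based half-open; VCF's 1-based positions are
converted on read and restored on write, and reported window spans are
1-based inclusive (BED output is 0-based half-open). Only biallelic SNP
records are ingested; multiallelic records are dropped rather than split,
because every downstream statistic is defined on a biallelic substrate and
splitting would introduce allele-ordering ambiguity. A site enters the
haplotype matrix only when every genotype at it is phased and fully called
(haplotype-identity statistics cannot tolerate missing data); the genotype
matrix keeps unphased and partially missing calls with per-site called-allele
bookkeeping, which is all the frequency-based statistics need.

Sample QC applies the two rules that are functions of the shipped metadata:
mean coverage ≥ 10× (boundary kept), and sex from the X:3R modal coverage
ratio — [0.4, 0.6] male, [0.8, 1.2] female, closed intervals, anything else
excluded. Upstream pipeline filters beyond these two are out of scope.

## Diversity statistics

π is computed from per-site allele frequencies with the n/(n−1) correction,
which equals exact pair enumeration (tested to 1e−12). θ_W = S/a₁. Tajima's D
uses the classical constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ derived from the
haplotype count. D is returned as NaN (flagged, never a crash) when S = 0 or
when the variance term degenerates (n = 2, where π ≡ S/a₁ identically).

Windowed summaries use non-overlapping SNP-count windows (default 1000 SNPs,
matching the H12 scan granularity); the point estimate is the mean over
windows and the 95% CI a delete-one-window jackknife — chosen over a
bootstrap for determinism; fewer than 5 windows flags the CI unreliable.
Per-base normalisation is available when a window span is supplied;
accessibility masking is not implemented, so per-base values assume fully
accessible spans.

Note a property of SNP-count windows: per-window π is driven by the allele
frequency spectrum, not by the mutation rate, so two *independent* site sets
with different θ have similar per-window π. Diversity ordering between
cohorts is only meaningful on a shared site axis (as in a joint VCF), where a
low-diversity cohort is monomorphic at many shared sites; the tests construct
their ordering fixtures accordingly.

## Garud H scan

Haplotype identity is exact string equality over the window — the definition
of the statistic; no mismatch tolerance. H1 = Σpᵢ², H12 merges the top two
frequencies, H123 the top three; missing classes count as frequency 0. The
invariant H1 ≤ H12 ≤ H123 ≤ 1 holds exactly. Windows default to 1000 SNPs,
non-overlapping, with a `step` override for moving windows; a trailing
partial window is kept and flagged if it covers at least half a window,
dropped otherwise. Peak calling (maximal runs of ≥ `min_contiguous` windows
with H12 ≥ `threshold`, defaults 2 and 0.1) is a convenience for locating
candidate sweeps; thresholds are configuration, not biology.

## Hudson F_ST

The per-site components use the finite-sample-corrected numerator and the
cross-population heterozygosity denominator; windows aggregate as the ratio
of averages ΣN/ΣD. The average of per-site ratios is deliberately not
offered — it is biased at low-diversity sites. Sites with fewer than two
called alleles in either cohort are skipped; sites monomorphic for the same
allele in both cohorts contribute N = D = 0 and are excluded from the
informative-SNP count; a window with ΣD = 0 yields NaN, flagged. The
estimator is unbiased, so small negative windows are expected near panmixia
and are not clipped. The numerator is grouped as
(p₁−p₂)² − (c₁ + c₂) so the estimate is bit-exactly symmetric under
population exchange.

## PCA

Per kept site (MAF ≥ 0.01, missingness ≤ 0.1 by default — declared, not
inferred from any reference analysis), dosages are mean-imputed and scaled to
(g − 2p̂)/√(2p̂(1−p̂)), unit variance under Hardy–Weinberg. The √(2p̂(1−p̂))
denominator differs from the √(p̂(1−p̂)) variant only by a global √2, which
rescales coordinates uniformly and leaves explained-variance ratios and all
separation statements unchanged. Decomposition is a deterministic full SVD
(no randomized solver), so PCA results carry no seed; component signs are
fixed by making each component's largest-magnitude site loading positive.
Degenerate rank returns fewer components, flagged. No LD pruning by default.

## Markers and CNVs

A marker is defined at codon level: gene, strand, the three genomic
coordinates of the codon in transcription order, and the reference codon on
the coding strand. Minus-strand variants are reverse-complemented into coding
orientation before substitution; translation uses the standard genetic code;
a variant whose reference allele contradicts the stored codon is a hard
consistency error. Frequencies are alt alleles over called alleles per
cohort; markers absent from the variant table are reported at frequency 0
with an absent-site flag, since absence is itself a surveillance result.
The bundled panel file is synthetic: real gene and substitution names
(Vgsc 995F/995S/R254K/N1570Y, Rdl, Ace1, Cyp4j5, Cyp6p4, Cpr K75N/T319N/A583S)
with placeholder coordinates, intended for testing against synthetic VCFs,
not for annotating real alignments.

CNV summaries report both carrier proportion (copy number > 2 against the
diploid baseline) and mean copy number, with the carrier proportion as the
default "frequency" and a fixation flag at carrier proportion 1. Emitting
both sides avoids committing to one semantics where conventions differ
between pipelines.

## Bioassay statistics

Raw mortality is 100·dead/exposed. Abbott correction applies when control
mortality lies in [5%, 20%]; above 20% the test is invalid — both cutoffs
follow the WHO tube-test protocol and live in module constants, not buried in
logic. Classification: < 90% resistant, 90–98% suspected resistance, ≥ 98%
susceptible. Confidence intervals are Wilson score intervals (the
single-proportion interval Newcombe recommends), without continuity
correction by default and with the corrected variant behind a flag; the k = 0
and k = n boundaries return exact 0 and 1.

The GLM is binomial with a logit link on site × insecticide cells with tubes
pooled (tube-level replication is not modelled; overdispersion handling is
out of scope). Fitting is IRLS via statsmodels with the convergence tolerance
tightened to 1e−12 so that the single-df Wald χ² agrees with the closed-form
2×2 computation to better than 1e−6. Per-term Wald χ² and p-values come from
joint tests of each term's coefficients. Fitted probabilities at the 0/1
boundary flag the fit non-converged (possible complete separation) and the
coefficients are returned with a warning rather than suppressed.

## Synthetic-data generators

The coalescent generator builds a Kingman genealogy (exponential waiting
times with rate k(k−1)/2, uniform pair merges) and drops mutations as a
Poisson process at rate θ/2 per unit branch length, each creating a new
biallelic site — infinite sites, no recombination within a window; windows
are independent. Site positions are drawn uniformly without replacement over
the window span and sorted. This is sufficient to validate the estimator
formulas; it does not emulate linkage patterns, recombination gradients, or
demography, so recovery tests certify the statistics, not their behaviour on
real chromosomes.

Sweep injection copies a random round(f·2N)-subset of columns from one core
haplotype and flips each copied allele with probability ε. Two ε regimes
matter. A recent hard sweep leaves hitchhiked haplotypes near-identical at
window scale, i.e. ε·E[S] ≪ 1; fixtures that claim near-certain per-window
detection (peak localization, the demo, the paired power check) use
ε = 0.001 at ~120-SNP blocks or θ = 10 windows (ε·E[S] ≈ 0.05–0.12). At
ε = 0.01 and larger windows, residual mutation fragments exact-identity
classes — measured paired-superiority power peaks around 94–95% across all
θ, because without recombination roughly 5% of neutral Kingman windows are
themselves sweep-like; at that ε the honest statement, and the one tested,
is that the *mean* H12 under sweeps clearly exceeds the neutral mean.

Balding–Nichols demes draw per-SNP ancestral frequencies from
Uniform(0.05, 0.95) — avoiding Beta degeneracy at extreme p — and per-deme
frequencies from Beta(p(1−F)/F, (1−p)(1−F)/F), so F equals the expected
Hudson F_ST. Sites are independent (no LD). Bioassay counts are binomial
under a logit-linear site + insecticide model.

All generators are deterministic given a seed. Neutral Tajima's D centres
only approximately at zero: its true mean at n = 10, θ = 10 is ≈ −0.07 (the
small-sample bias of the normalization; cross-checked against an independent
coalescent implementation), which high-replicate tests of "mean D ≈ 0" will
resolve — the package's property test checks centering at a resolution
(300 replicates) consistent with the approximation.

## Pipeline and reproducibility

A YAML config with explicit seeds drives all stages in dependency order.
Every output TSV carries a comment header with the tool version and
parameters (never timestamps), and the manifest maps outputs to SHA-256
checksums; identical config and inputs reproduce identical manifests. The
demo bundle emulates the study design at desk scale — four cohorts of 20
diploids over ten 120-SNP Balding–Nichols blocks (background F = 0.05), a
hard sweep (f = 0.6, ε = 0.001) injected into one cohort in one block, three
marker sites with known per-cohort frequencies, an amplification fixed in
the two Kimpese-named cohorts, and bioassays in which the Kimpese site is
engineered most resistant. These sizes keep the full suite and the
acceptance script in the tens of seconds while leaving every recovery
comfortably resolved.

## Known limitations

- No recombination or LD in any generator; window independence is an
  idealisation.
- No accessibility masks; per-base diversity assumes fully accessible spans.
- The marker panel ships with placeholder coordinates; real use requires a
  panel built from a genome annotation.
- CNV calls are consumed, not called; coverage-based CNV detection is out of
  scope.
- The bioassay GLM pools tubes; tube-level overdispersion is not modelled.
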