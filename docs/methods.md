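# Methods

`sweepscan` detects genomic regions under recent selection by contrasting two
labeled populations with three complementary scans — XP-EHH, EigenGWAS and
EMMAX — and turns per-SNP scores into annotated candidate regions. This note
describes the statistical models, the conventions that had to be fixed where
the methods literature leaves choices open, and what the synthetic data
generator does and does not emulate.

## Data model and filtering

Genotypes are alt-allele dosages in {0, 1, 2} with an explicit missing
sentinel; phased haplotypes are binary 2N × M panels with no missing entries
(phasing and imputation are upstream of this package). Coordinates are
1-based inclusive everywhere, and interval length is defined as
`end − start` bp. That convention is forced by the region caller: a single
outlier SNP extended by the default ±10 kb flank must yield a region of
exactly 20.000 kb.

SNP filters: QUAL ≥ 20, call rate ≥ 90 %, pooled-sample MAF ≥ 5 % (all
inclusive bounds), and membership of a declared set of assembled
chromosomes — the practical reading of "fixed chromosome" filtering, i.e.
unplaced scaffolds are excluded. Filter attribution is first-fail in the
fixed order qual → chromosome → call rate → MAF, so the report's counts are
deterministic. MAF is computed on the two populations pooled because a single
merged SNP set feeds all scans.

## PCA and LD

PCA standardizes each variant (center, divide by the dosage SD; monomorphic
columns are skipped) and decomposes the sample × sample covariance;
variance explained is eigenvalue over trace. Standardized rather than merely
centered PCA is the population-genetics norm and keeps the eigenvectors
consistent with the EigenGWAS phenotypes. Missing dosages are mean-imputed
per variant for PCA and the regression scans only; the haplotype scans never
see missing data by construction.

LD is the squared Pearson correlation r² of dosage vectors for
intra-chromosomal pairs within 1 Mb (configurable), computed per population.
The decay curve bins pairs by distance (default 10 kb bins) and averages
per-chromosome bin means with equal chromosome weights — the literal reading
of "means across all chromosomes" — with pair-weighted pooling available
behind a flag. The LD extent at a threshold (default r² = 0.3) is linearly
interpolated between the bracketing bin centers; a curve that starts below
the threshold has extent 0, and one that never reaches it reports
"beyond range" (`None`) rather than a number.

## XP-EHH

EHH at distance x from a core SNP is the probability that two haplotypes
drawn without replacement are identical at every marker between the core and
x. Two conventions had to be fixed:

* **Core allele.** EHH is unconditional on the core allele and the core
  column is excluded from the identity check, so EHH(0) = 1 exactly and the
  curve is non-increasing. This is the cross-population variant's
  convention; allele-stratified EHH of the single-population statistics
  (iHS, REHH) is deliberately out of scope.
* **Integration boundary.** Both populations' integrals stop at the first
  marker where EHH computed on the *pooled* panel drops below a cutoff
  (default 0.05). A shared boundary is required for ln(I_A/I_B) to be
  comparable across sites; it also makes the statistic exactly antisymmetric
  under swapping the populations (the raw score is computed as
  log I_A − log I_B so the negation is bit-exact).

Distance is physical (bp). With a constant recombination rate genetic and
physical distance differ by a scale factor that cancels in the log ratio.
Integrals use the trapezoid rule anchored at (0, 1). Cores where the pooled
EHH never reaches the cutoff on either side are unscorable; cores truncated
by a chromosome end on one side are scored but flagged, and a strict mode
drops them instead.

Raw scores are normalized genome-wide (not per chromosome and not
frequency-binned — the simplest single-normal null) to mean 0, SD 1, and
two-sided p-values come from the standard normal: p = 2·(1 − Φ(|z|)).

## Region calling

Outlier loci are scorable SNPs with p strictly below alpha (default 0.01),
split by the sign of z: positive means longer haplotype homozygosity in the
observed population. Same-sign outliers with inter-position distance
strictly under 10 kb merge transitively into sections; sections gain ±10 kb
flanks clipped to [1, chromosome length]. The 10-kb flank is the unique
choice consistent with single-SNP regions of exactly 20.000 kb under the
end − start length convention. When flank extension makes same-sign regions
touch, a post-pass merges them (on by default); opposite signs never merge
because they indicate selection in different populations. Summaries report
kb with 3-decimal formatting, per chromosome and sign, plus genome fraction
given a chromosome-sizes table.

## EigenGWAS and genomic control

The EigenGWAS phenotype is an eigenvector of the genotype data itself (by
default components 2–5 for scanning; EV1 on strongly diverged data is
dominated by the between-population axis and is inflated genome-wide).
Each SNP is tested by OLS with intercept; the Wald chi-square on 1 df uses
the per-marker residual variance with n − 2 df. Drift inflates the null
distribution, so genomic control divides every chi-square by
λ_GC = median(χ²)/0.4549364 (the 1-df chi-square median) and recomputes
p-values; by construction the corrected median equals the null median.
Eigenvector sign is arbitrary: flipping it negates betas and leaves
p-values unchanged. No automatic rule decides which eigenvectors are
"noise"; that judgement is left to the user.

## EMMAX

The mixed model is y ~ N(Xβ, σ_g²K + σ_e²I). Kinship K is either mean IBS
sharing (1 − |d_i − d_j|/2 averaged over sites non-missing in both samples)
or the standardized cross-product (diagonal ≈ 1 + inbreeding). Variance
components are fit once by REML under the null via one spectral
decomposition of K and a deterministic 1-D search over δ = σ_e²/σ_g²:
a 100-point log-spaced grid on [1e−5, 1e5] followed by golden-section
refinement between the bracketing grid points. Per-marker tests are then
generalized least squares in the eigenvector-rotated space with the
components held fixed (the expedited approximation; exact per-marker REML is
out of scope). Weights are formed directly as 1/(σ_g²S_i + σ_e²), so σ_g² = 0
degrades gracefully to uniform weights and the scan reduces exactly to the
OLS scan — a tested contract. With K = I the two components are only
identifiable through their sum, which matches the OLS residual variance.

## Annotation

Genes attach to regions on any overlap (≥ 1 shared bp); QTL matching instead
requires full containment in either direction, because the two rules are
genuinely different in the procedure this package implements. QTL cleaning
first drops input intervals longer than 1 Mb (strict >), then iteratively
merges pairs overlapping by more than 50 % of the shorter interval (a
reciprocal-overlap mode is available) into their union, concatenating trait
labels, until no pair qualifies. Merged products are kept even if they
exceed 1 Mb — the cleaning produces "one larger QTL" — so the procedure is a
fixed point exactly when merged products stay under the cap, the regime the
tests exercise. Term enrichment is a plain upper-tail hypergeometric test
(P(X ≥ k)), significant at raw p < 0.05; a Benjamini–Hochberg column is
emitted for information only and plays no role in the significance flag.

## Synthetic data generator

The generator emulates the structure the scans consume, at desk scale:

1. ancestral frequencies Uniform(maf_floor, 1 − maf_floor);
2. population frequencies from the Balding–Nichols distribution
   Beta(p(1−F)/F, (1−p)(1−F)/F) at the target F_ST;
3. per population, `n_founders` founder haplotypes drawn site-wise;
4. sample haplotypes built by Markov founder-copying (Li–Stephens-flavored)
   with per-bp switch rate `copy_switch_rate`, which creates decaying LD;
5. optionally a hard sweep: a carrier fraction of one population's
   haplotypes is overwritten with a single sweep haplotype over
   [focal − L, focal + R], L and R exponential with mean `erosion_mean_bp`
   per carrier, emulating recombination erosion of the swept flanks.

Everything is driven by one seeded `numpy` generator; identical seeds give
byte-identical output.

Defaults are the study conditions: two populations of 50 diploid samples,
two 5-Mb chromosomes with 2,000 SNPs each, F_ST 0.2, 30 founders per
population, switch rate 1e−5/bp, sweep carrier fraction 0.9 with 200-kb
erosion. Thirty founders were chosen because the founder bottleneck adds
(1−F)/n_founders of extra drift on top of the Balding–Nichols target; at 30
founders that increment (~0.03) keeps the realized Hudson F_ST within the
±0.05 recovery band around the target, while the mosaic copying still
carries enough LD for the haplotype scans. Strong-LD experiments (LD-decay
curves with extents in the tens of kb) instead use few founders (e.g. 4)
and slower switching, where baseline r² between same-segment sites is high.

What the generator does **not** emulate: realistic demography or coalescent
genealogies, mutation/recombination heterogeneity, allele-frequency spectra
of real SNP ascertainment, genotyping error, or unphased/missing haplotypes.
Passing tests therefore demonstrate the correctness and calibration of the
statistics under a controlled null and a planted signal — not discovery
performance on any real breed comparison.

## Problem sizes used in tests

The test suite runs the complete pipeline but scales simulation sizes to
desk scale as the package's own choice of test conditions: the sweep-power
check uses 50 seeded replicates of 25 samples/population over two 2.5-Mb
chromosomes of 1,000 SNPs (the default per-bp SNP density and all sweep
parameters unchanged); heritability recovery uses n = 200 samples and 50
phenotype draws; calibration comparisons use 50 replicates of 40 samples ×
400 SNPs. `scripts/acceptance.py` reports the same quantities from a single
full-default run plus 20-replicate summaries.

## Known limitations

* The XP-EHH scan is O(cores × window × haplotypes); very dense panels with
  long-range LD are slow in pure Python/numpy, though the partition-refine
  step is vectorized.
* Only biallelic SNPs are supported; multi-allelic records are rejected (or
  dropped on request), never split.
* The EHH cutoff, normalization scope and core-allele handling are declared
  defaults, all configurable; other published implementations make slightly
  different choices, so raw scores are comparable only under matching
  settings.
* No genetic-map support: a non-constant recombination rate would change
  relative integrals in a way physical distance cannot capture.
* FDR control is intentionally absent from region calling (a fixed nominal
  alpha is the procedure being implemented); the enrichment module emits a
  BH column for information only.
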