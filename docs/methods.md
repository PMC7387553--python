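# Methods

## Study design emulated by the generator

The synthetic module reproduces the structure of a paired immune
stimulation study: one cohort of genotyped individuals (default 135),
each measured in up to four conditions — resting and LPS-stimulated
myeloid cells, resting and PHA-stimulated T cells — with unequal
post-QC retention per condition (defaults 116/125/126/127 of 135, i.e.
the fractions 0.859/0.926/0.933/0.941) and a core subset (default
95/135) present in all four. Samples of one individual share the
individual id across conditions, which is what the response-eQTL mixed
model and its permutation scheme rely on.

### Genotypes

SNPs are biallelic with generating MAF uniform in [0.10, 0.50] — the
analysis-stage frequency floor of 10% is built into the generator so
every planted effect sits on a testable variant. LD is produced by a
Gaussian copula: per block (default 20 SNPs) a latent standard-normal
Markov chain is thresholded at each SNP's Hardy–Weinberg quantile; two
independent haplotype draws per individual sum to the dosage, so
Hardy–Weinberg proportions hold by construction. Thresholding attenuates
correlation, so the latent adjacent correlation is solved numerically
(bivariate-normal orthant inversion) to hit the configured *dosage*
correlation. SNPs within a block share a block-level MAF with ±0.02
jitter: binary variables with very different frequencies cannot be
highly correlated, so heterogeneous MAFs would cap the achievable LD —
and frequency similarity within a haplotype block is also what real data
look like. Monomorphic columns after sampling are redrawn i.i.d. and
logged. The generator's LD model is a simulation knob, not an estimate
of any real panel's LD structure.

### Expression

Per condition, expression of gene *g* for sample *i* is

    y = condition effect + sex·b_sex + PCs·b_pc + factors·b_f
        + genotype effect + u_individual + N(0, noise_sd)

with 14 covariates (sex ~ Bernoulli(0.5); three genotype-PC proxies and
ten latent factors ~ N(0,1), the factors with small loadings on all
genes, default s.d. 0.15) mirroring the 14-covariate design of the
emulated study with latent factors in place of inferred ones. Genotype
effects are condition-specific: each planted cis pair carries a resting
and a stimulated slope within one cell type; response effects differ
between the two (sign-flips have beta_stim = −beta_rest). Defaults:
effect magnitude ~ |N(0.8, 0.13)| s.d./allele, random intercept s.d.
0.5, noise s.d. 1.0.

Planted trans trios are mediator chains: the trans gene receives
b × (realised mediator expression) + c′ × dosage, so the indirect path
carries the mediator's noise, as a real cis-mediated trans effect would.
Trio effect sizes default to a ~ |N(1.6, 0.1)| and b ~ |N(0.8, 0.05)|:
trans associations that survive genome-wide correction in a cohort of
~120 are by construction the extreme tail, and these values put the
planted trios at that detectability margin rather than far below it.
MR-causal genes receive several (default 4) causal cis SNPs in distinct
LD blocks (effect ~ |N(1.0, 0.05)| per allele) so that LD-pruned
instruments remain, and transmit effect 0.3 per unit of genetic score to
the disease liability.

### GWAS

A fresh cohort (default 20 000) is drawn from the same LD model; the
liability is the sum of direct planted locus effects (shared loci reuse
the eQTL causal SNP; distinct loci use a SNP from another LD block in
the same window), causal-gene genetic scores, and standard-normal noise.
Marginal per-SNP OLS yields beta/SE/p for every panel SNP. An
allele-flip export mode swaps effect/other alleles with negated beta for
a random subset, for harmonisation round-trip tests.

### What the generator does not emulate

Probe-level microarray intensities, negative-control background
structure, population stratification beyond PC proxies, sex chromosomes,
non-Gaussian expression noise, and realistic genome-scale LD. Passing
tests therefore demonstrate the correctness and calibration of the
inference machinery under the stated generative model, not robustness to
real-data artefacts.

## Preprocessing

Genotype QC removes SNPs with missing call rate > 1%, MAF < 1%, or a
1-d.f. Hardy–Weinberg chi-square p < 10⁻⁶ (on dosages rounded to hard
calls, no continuity correction); the analysis filter keeps MAF ≥ 10%.
The expression path assumes background-corrected positive intensities
(a microarray negative-control model is deliberately out of scope; the
positivity check documents the assumption). Fixed order: outlier-sample
removal (detectable-probe count outside median ± 2·IQR) → probe
missingness (≥ 5 samples) → detectability (detection p ≤ 0.01 in ≥ 2.5%
of any one condition's samples or ≥ 5% of all samples; note the second
branch can only bind when its threshold is below the first, since the
overall fraction is a convex combination of per-condition fractions) →
one probe per gene (highest mean intensity, ties to the
lexicographically smaller probe id) → within-condition quantile
normalisation + log2 → rank-based inverse normal transform per gene
(Blom offset 3/8, average ranks for ties; the offset is a convention
choice, and Blom is the common default). Latent technical covariates are
the top 10 expression PCs per condition — a deterministic, dependency-free
stand-in for factor-model inference that plays the same role.

## Cis mapping and the hierarchical correction

The scan residualises expression and dosage on the covariates once per
condition (Frisch–Waugh–Lovell), giving exactly the full-model OLS
dosage coefficient, SE and t with n − k − 1 residual d.f.; p-values use
the t distribution (better at n ≈ 120 than a normal approximation).
Window arithmetic is 1-based and inclusive, |pos − TSS| ≤ 10⁶.
M_eff per gene is the sum over consecutive ≤ 200-SNP chunks of the
minimal eigenvalue count explaining ≥ 99% of the dosage correlation
variance, capped at the SNP count (chunk size and variance fraction are
config-exposed). Top-SNP ties break by smallest p, then largest |beta|,
then smallest position, making outputs deterministic. When no gene
passes BH the global cutoff and nominal thresholds are reported as NA.

## Conditional analysis

Forward: re-scan the cis window conditioning on all selected SNPs (added
to the covariates), select the new top SNP while anything stays below
the gene's nominal threshold; iterations are capped (default 10) since
genes with many independent signals are rare. Backward: each selected
signal is re-tested conditioning on all others; the signal is
represented by the top SNP of that leave-one-out re-scan and retained if
it stays below the threshold. Cross-condition: condition B's window is
re-scanned adjusting for A's top eSNP; "independent" iff anything stays
significant, otherwise "shared" — explicitly shared *or underpowered*,
since absence of a residual signal cannot be distinguished from lack of
power. Both directions of each condition pair are computed and reported.

## Response eQTLs

Test selection per cell type: eGenes significant in one condition
contribute that top eSNP; in both conditions, both eSNPs when their
r² < 0.8, otherwise only the more significant one. The mixed model is
fit by a profiled-REML random-intercept solver: for a single variance
ratio λ = τ²/σ², GLS at fixed λ is closed-form via groupwise rank-one
updates, and REML reduces to a 1-D bounded optimisation. This makes a
refit ~1 ms, which is what renders a 1000-permutation null affordable;
the solver is cross-checked against statsmodels' MixedLM in the test
suite (coefficients and variance components agree; our SEs are the
exact GLS covariance at the REML estimates). Degenerate variance
structures fall back to OLS with individual fixed effects, logged.
Permutations swap each individual's full condition pair (covariates and
pairing preserved exactly); the covariate×condition interactions are
rebuilt and the model refit in full each time. The observed-vs-permuted
comparison uses |Wald z| of the interaction. Optional early stopping
once s ≥ 50 permuted exceedances (the p-value can no longer reach
significance at any FDR level in use) affects runtime only.

## Trans scan and mediation

The cross-chromosome scan reuses the cis machinery; only rows with
p < 10⁻⁵ plus every gene's minimum are retained, which is sufficient
for all three correction schemes at any realistic scan size (no
rejection boundary approaches the storage threshold). Scheme 1 applies
BH over all pair p-values using the full test count as the BH
denominator; scheme 2 multiplies per-gene minima by 10⁶ (the genome-wide
effective SNP count 0.05/5·10⁻⁸), capped at 1, then BH over genes;
scheme 3 uses 5·10⁻⁸ divided by the gene count. The genome-wide FDR
scheme is the default reported one (least conservative). Mediation trios
are restricted to trans-eSNPs that are also significant cis-eSNPs
(optionally via LD proxies at r² ≥ 0.8); the decomposition identity
total = a·b + c′ holds to machine precision because both regressions
share the same covariates. The bootstrap resamples individuals, not
samples, respecting the sampling unit; the p-value is the two-sided
sign-crossing probability of the bootstrap ab distribution (percentile
construction, config-exposed), with degenerate constant-dosage resamples
redrawn. The proportion mediated is reported clipped to [−1, 2] with the
raw ratio retained, since the ratio is unstable near zero totals.

## Colocalisation

ABFs use prior effect variances W = 0.15² (quantitative/eQTL) and 0.2²
(binary GWAS, log-odds scale), taken directly rather than derived from
sample sizes. All evidence accumulation is in log space (log-sum-exp and
a guarded log-difference for the H₃ cross term); single-SNP loci have
PP₃ = 0 identically. Locus selection: any significant cis-eSNP with
GWAS p ≤ 10⁻⁶, a 400-kb window centred on the top eSNP (inclusive
boundaries), intersection of both summary sets, < 25 shared SNPs
skipped. Decisions: underpowered if PP₃+PP₄ < 0.8; colocalised if
PP₄/PP₃ ≥ 5; else distinct; a sensitivity sweep over p₁₂ ∈ 10⁻⁹…10⁻⁵
records whether the decision is robust (PP₄ is monotone in p₁₂
analytically). GWAS alleles are harmonised to the panel's alt allele
first, with strand-ambiguous SNPs dropped.

## Mendelian randomisation

Harmonisation aligns outcome effect alleles to the exposure's, flipping
betas on swaps and removing palindromic (A/T, C/G) variants and allele
mismatches with reason codes. Greedy LD pruning by ascending exposure p
at r² < 0.1; pairs with fewer than 3 surviving instruments are skipped.
IVW is the 1/se² weighted regression through the origin — algebraically
the precision-weighted mean of Wald ratios — with a multiplicative
random-effects SE (scaled by residual dispersion when > 1): exposure
sampling error induces heterogeneity that a purely fixed-effect SE
ignores, and without the correction the IVW CI undercovers. The weighted
median uses first-order ratio SEs for weights and a 1000-draw seeded
parametric bootstrap for its SE; the weighted mode uses a Gaussian
kernel with the modified-Silverman bandwidth (φ = 1) and the same
bootstrap. MR-Egger orients exposure betas positive, fits a weighted
regression with intercept, floors the residual SE at 1 (no reward for
under-dispersion) and uses t inference; its intercept p is the
pleiotropy test. The mode's bandwidth and Egger's floor make those two
methods deliberately conservative under the null (type-I error ~1–3% at
nominal 5%); IVW and the median sit near nominal. The Egger intercept
test has useful power only with many instruments spanning a wide range
of exposure effects — the intercept is an extrapolation to
beta_exposure = 0 — which the pleiotropy benchmarks reflect. Verdicts:
pleiotropy exclusion at intercept p ≤ 0.05; suggestive causality at
≥ 3 of 4 methods p ≤ 0.05; no multiple-testing correction on verdicts.
When a gene is instrumented in several conditions, the condition with
the most instruments is the reported one (config-overridable).

## Replication rate

Storey's π₀ via the smoother: π₀(λ) = #{p > λ}/(n(1−λ)) on the grid
0.05…0.95 (step 0.05), a cubic polynomial fit evaluated at the largest
λ, clipped to [0, 1]; π₁ = 1 − π₀. The smoother (not the bootstrap
variant) is deterministic. Discovery pairs untested in the replication
dataset are counted and excluded. The output carries the caveat that π₁
uses p-values only — neither direction nor magnitude of effects.

## Pipeline, determinism and numerical choices

Every stage is a pure function of (inputs, config, seed); one global
seed is split into stage-scoped streams by a CRC-based key so stages are
individually reproducible across processes. Genomic positions are
1-based inclusive internally; BED-like output converts to 0-based
half-open at the boundary. The manifest records the config snapshot,
seeds, per-stage row counts and output hashes; identical seeds reproduce
identical hashes. All paper-style thresholds (1 Mb window, 5% FDR,
r² 0.8 and 0.1, GWAS p 10⁻⁶, p₁₂ 10⁻⁶, 1000 permutations, 10 000
bootstrap draws, ≥ 3 instruments, MAF ≥ 0.10) are named config keys.

## Benchmark problem sizes

The calibration and recovery benchmarks (package module `benchmarks`,
driven by the acceptance script and suite) run at desk scale as the
package's own choice of profile: global-null calibration at 500 genes ×
50 cis SNPs (10 seeds) for the hierarchical procedure, 500 genes × 800
SNPs for the trans scheme, and 100–200 interaction tests × 100
permutations for the reQTL null; recovery at n = 120–126 with 20–50
seeded replicates. Null calibration is summarised as the proportion of
tests falsely declared significant: under a pure global null the
per-seed false-discovery proportion is 0/1-valued (any rejection makes
it 1), so at ten seeds that statistic cannot resolve a bound below 0.1,
while the proportion of false calls can. Effects stated in s.d./allele
are planted on an approximately unit-variance expression scale so the
unit survives rank-normalisation.

## Known limitations

Single-causal-variant colocalisation only (no multi-causal credible
sets); two-condition interaction models only; no exposure–mediator
interaction or unmeasured-confounding sensitivity in the mediation
stage; the trans scan stores only sub-threshold rows, so full p-value
histograms for trans pairs are not retained; π₁ ignores effect signs by
construction.
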