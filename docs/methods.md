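# Methods

## Model

The association model is the standard GWAS linear mixed model

    y = Xβ + u + ε,   u ~ N(0, σg²K),   ε ~ N(0, σe²I),

with X = [1 | covariates | tested SNP] (c columns in total). Marginally
y ~ N(Xβ, σg²K + σe²I). The assumptions that matter in practice are (i)
Gaussian residuals — deliberately violated by the gamma settings of the
simulator — and (ii) that a single genome-wide K captures confounding
relatedness.

### Variance components (null model, REML)

σg² and σe² are estimated once under the null design X₀ = [1 | covariates]
and reused for every marker test (the EMMAX/FaST-LMM single-fit
approximation; components are deliberately *not* refitted per SNP). With the
eigendecomposition K = UΛUᵀ the restricted likelihood is profiled over the
variance ratio δ = σe²/σg²: given δ, the GLS residual sum of squares in the
rotated coordinates yields σ̂g² = RSS/(n − c₀) in closed form. δ is searched
on a 100-point log-spaced grid over [1e-5, 1e5] followed by bounded scalar
refinement between the best grid point's neighbours; ties break toward
smaller δ. REML (not ML) is used, as is standard in this model family, and
grid-plus-refinement is preferred over a generic optimizer for exact
reproducibility. Degenerate cases: a zero-residual null design pins σe² at
1e-10 with a warning; near-constant eigenvalues (K ∝ I) make only σg² + σe²
identifiable, which is logged.

### Batched F-tests

Rotation by Uᵀ diagonalizes the covariance, leaving a weighted least-squares
problem with weights 1/(σg²λᵢ + σe²). The null design is orthonormalized
once (QR); each SNP's statistic needs only its rotated, weighted column
residualized against that basis, so thousands of SNPs are tested with a few
matrix products. F = (RSS₀ − RSS₁)/(RSS₁/(n − c)) with df (1, n − c).
Results are bitwise independent of the batch size (an explicit contract,
tested at batch sizes 1, 7 and m). SNPs numerically collinear with the null
design (relative residual norm below 1e-10) report β = 0, p = 1 and are
flagged rather than raised, so permutation scans never abort mid-batch.
p-values are floored at the smallest positive double to stay in (0, 1].

## maxT permutation thresholds

For each of q permutations the full scan is repeated and the minimum p-value
recorded; the threshold at level α is the ⌊αq⌋-th smallest minimum p-value
(Westfall–Young convention; ⌊αq⌋ = 0 falls back to the smallest minimum with
an "underpowered" warning). q < 20 is rejected outright. Permutations are
drawn uniformly with replacement from the symmetric group; a seed is
mandatory on the command line.

Two strategies:

- **fixed_effects** (default): one shared row permutation π is applied to
  the covariate and SNP columns of X; y, K and hence the null fit stay
  fixed. This equals jointly permuting y and the rows/columns of
  σg²K + σe²I (the package tests this equivalence permutation-by-permutation
  against a brute-force explicit-covariance implementation; permuting X's
  rows by π corresponds to relabelling (y, Σ) by π⁻¹). Implementation note:
  Uᵀ S[π] = U[π⁻¹]ᵀ S, so whole chunks of permutations are rotated with one
  matrix product against the dosage matrix; only the per-permutation maximum
  F is converted to a p-value.
- **phenotype_only**: y is permuted. Because this breaks the y–K link, the
  variance components are refitted for every permuted phenotype (the cached
  eigendecomposition makes each refit cheap); the genotype rotation is
  computed once.

## Synthetic data

The generator emulates a structured plant-association panel at its default
scale: n = 200 individuals, m = 2000 biallelic SNPs, 3 subpopulations at
Fst = 0.2, placed on 5 chromosomes at 1 kbp spacing.

- **Genotypes**: Balding–Nichols — ancestral frequencies ~ U(0.05, 0.95),
  subpopulation frequencies ~ Beta(p(1−Fst)/Fst, (1−p)(1−Fst)/Fst), diploid
  dosages ~ Binomial(2, p). Loci are independent (LD-free) by default; an
  optional first-order copying parameter introduces local LD for
  window-logic tests.
- **Kinship**: the standardized kernel K = ZZᵀ/m with per-SNP empirical
  centring and scaling (ddof = 0), so mean(diag K) = 1 and σg² is on the
  phenotypic scale. The empirical SD is used instead of √(2p(1−p)) for
  robustness at small n. No further normalization (e.g. trace/n) is applied.
  Column centring makes K exactly singular along the all-ones direction, so
  K is stabilized by adding δ·I, δ doubling from 1e-8 until the smallest
  eigenvalue reaches 1e-8 (δ > 1e-2 is an error).
- **Phenotypes**: y = sβ + Cu + ε with C the Cholesky factor of K and
  u ~ N(0, I). Noise is Gaussian or mean-centred gamma with shape
  k ∈ {4, 3, 2, 1, 0.5} (skewness 2/√k). The noise is rescaled so the
  background explains exactly 30% of the realized non-SNP variance, then one
  causal SNP (MAF > 0.05, drawn uniformly) is added with β scaled so it
  explains exactly 20% of the realized total variance. Enforcing the
  fractions on realized vectors (rather than in expectation) turns
  "approximately 30%/20%" into an exactly testable contract; the 30% is
  computed on (background, noise) before the SNP is added, matching the
  order in which the components are constructed. The full design is 6
  settings × 100 replicates = 600 phenotypes, with per-replicate seeds
  derived from a master seed by fixed offsets.

What the simulator does *not* reproduce: realistic linkage disequilibrium
(coalescent structure), allele-frequency spectra of real panels, multiple
causal loci, or genotyping error. Passing tests therefore demonstrate the
statistical machinery under a clean, structured, LD-free panel — not
performance on any real species' genome.

## Evaluation

A significant SNP within ±10 kbp (inclusive) of the causal marker on the same
chromosome is a true positive, anything else below threshold a false
positive; the symmetric-window reading matches the ~10 kbp LD-decay rationale
and the independent-locus gap rule. FDR = FP/(TP+FP) per replicate
(undefined, and excluded from averages, when there are no hits); the
phenotype-wise pFDR of a setting is (# replicates with an FP)/(# with a TP +
# with an FP), where one replicate can count on both sides. Independent loci
are greedy per-chromosome clusters split by gaps > 10 kbp. Comparators:
Bonferroni α/m and the Benjamini–Hochberg step-up rule (applied per
phenotype, never pooled across phenotypes; implemented directly because the
data-dependent threshold p(k) is part of the contract, and cross-checked
against statsmodels). Residual normality uses the case-3 Anderson–Darling
statistic with the small-sample correction A²(1 + 0.75/n + 2.25/n²) and the
standard piecewise exponential p-value approximation, clamped to [1e-12, 1]
(the statistic is cross-checked against scipy, the p-value against R's
nortest during development). Outcome pairs of independent-locus counts
(Bonferroni, permutation) are classified into seven mutually exclusive
categories using "up to 10 independent loci is reasonable" as the yardstick.

## Reference study designs and problem sizes

`permlmm.study` packages four deterministic experiment drivers, run by the
test suite and by `scripts/acceptance.py` at these scales (chosen to keep a
single-CPU run in the tens of minutes while leaving the conclusions stable):

- **FWER calibration**: 200 independent null datasets (n = 200, m = 2000,
  structured genotypes, 30%-heritable background + Gaussian noise, no causal
  SNP), maxT threshold with q = 200 at α = 0.05; the empirical FWER is
  checked against the 99% binomial band [0.015, 0.10] around 0.05.
- **Skew trends**: 6 noise settings × 10 replicates on one shared panel,
  q = 200; medians of the permutation thresholds should tighten, and mean
  Bonferroni false-positive counts should grow, as skew increases (Spearman
  ρ > 0). Note the false-positive trend is the weaker signal at m = 2000:
  the Bonferroni cut is only 2.5e-5, where F-tests at n = 200 are fairly
  robust, so counts are small and the rank correlation rests on the most
  skewed settings.
- **Threshold stability**: one gamma(1) phenotype, 10 repeated threshold
  computations at q ∈ {100, 500, 2000}; the spread (max − min) must shrink
  monotonically.
- **Heritability recovery**: 50 draws of y ~ N(0, 0.7K + 0.3I) at n = 200;
  the mean REML estimate of σg²/(σg²+σe²) must land within ±0.15 of 0.7.

## Numerical choices and limitations

- δ-grid bounds [1e-5, 1e5] cap the detectable variance ratios; phenotypes
  outside that range hit the grid edge (logged via the fit's δ).
- The kinship jitter ceiling (1e-2) deliberately refuses matrices that are
  badly non-PSD rather than masking data errors.
- Minor-allele orientation flips (dosage → 2 − dosage when frequency > 0.5)
  change β's sign but neither p-values nor K; MAF is always reported folded.
- Genotype coordinates are 1-based inclusive bp (PLINK convention); the
  ±10 kbp window logic inherits this.
- Missing genotype calls are accepted at read time only and mean-imputed per
  SNP before analysis.
- The phenotype_only strategy ignores population structure by construction;
  it is provided for comparison and speed, not as the recommended default.
- Exact per-SNP variance re-estimation (EMMA-style), multi-locus models and
  adjusted per-SNP permutation p-values are out of scope.
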