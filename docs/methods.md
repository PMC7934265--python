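# Methods

This note records the models, estimators and numerical choices behind
`episcore`, and what the synthetic-data experiments do and do not establish.

## Data model

Genotypes are biallelic minor-allele counts in {0, 1, 2} with an explicit
missing code. The counted (A1) allele is the minor allele; at MAF exactly 0.5
the tie is broken lexicographically by allele. Coordinates are 1-based on a
single assembly; no liftover is attempted. Case-control status is binary;
covariates are sex, age, genotyping batch and the leading genotype principal
components. Imputation-uncertainty filtering is represented only as a
pre-existing missing mask on input genotypes — imputation itself is out of
scope.

## Quality control

* **Sample filters** run before SNP filters: genotype missing rate > 0.2, or
  heterozygosity rate (heterozygous calls / non-missing calls) more than 3
  SDs from the cohort mean. A zero or undefined SD disables the
  heterozygosity rule rather than removing everyone. The filter pair is
  idempotent: a second application removes nothing.
* **SNP filters**: missing rate > 0.1, MAF < 0.05, or Hardy–Weinberg exact
  p < 1e-6. The HWE exact test conditions on allele counts and sums the
  probabilities of all heterozygote counts no more probable than the
  observed one. HWE is computed on controls only by default — the standard
  precaution against discarding genuinely disease-associated SNPs; a flag
  switches to all samples for workflows that prefer it.
* **Annotation selection** keeps SNPs within 5 kb of a protein-coding gene
  with a deleteriousness (CADD-like) score ≥ 15; both thresholds are
  parameters.
* **LD** is composite r²: the squared Pearson correlation of dosages over
  pairwise-complete samples, computed on all samples (cases + controls).
* **PCA** mean-imputes missing calls per SNP, standardizes columns
  (monomorphic columns contribute zeros), and takes coordinates from the
  SVD; each axis's sign is fixed by making its largest-magnitude SNP loading
  positive, so results are reproducible across runs and platforms.

## Interaction tests

All three tests consume the 3×3×2 genotype-by-status contingency table of a
pair, tallied over samples observed at both SNPs (pairwise-complete
deletion). Pairs with any of the 18 cells below 3 are excluded before
testing and do not count toward the FDR denominator. Screening tests omit
covariates, as is standard for contingency-based epistasis scans; covariate
adjustment happens in the post-hoc genotypic test.

* **Logistic product term.** Because the model depends on the data only
  through the nine genotype patterns, the per-sample likelihood is maximized
  on the aggregated (grouped-binomial) table with batched Newton–Raphson
  (tolerance 1e-10 on the step, 60 iterations, ridge 1e-10 on the Hessian,
  steps clipped to ±5 for stability); the 1-df LRT compares against the
  main-effects-only fit. Non-converged fits are flagged and reported as
  missing rather than dropped silently. An allelic (PLINK-dialect) coding is
  intentionally not implemented; the additive-dosage product term is the
  package's single screening dialect.
* **BOOST.** The homogeneous-association log-linear model (all three two-way
  margins, no three-way term) is fitted by iterative proportional fitting to
  a per-cell convergence of 1e-8 (hard failure after 10,000 sweeps); the
  statistic is twice the saturated-vs-fitted log-likelihood gap, referred to
  χ²(4). The screening-bound shortcut of the original algorithm is treated
  as an optimization, not the contract: every reported p comes from the full
  statistic. Tables are built from per-genotype bit planes and popcounts of
  plane conjunctions; the batched all-pairs scan uses an algebraically
  identical BLAS formulation, and both are tested to agree exactly with a
  naive tally.
* **Joint effects.** For each status stratum the four log odds ratios of the
  2×2 subtables anchored at the (0, 0) cell are compared between cases and
  controls through the quadratic form d′V⁻¹d, V the sum of the two
  delta-method covariances, referred to χ²(4). Variance terms use
  1/(n + 0.5) instead of 1/n: at the small cell counts the cell filter
  admits (≥ 3), E[1/n] exceeds 1/E[n] and the raw-count variance makes the
  test measurably conservative (≈ 0.042–0.044 rejection at the nominal
  0.05); the half-count (Agresti-style) correction restores the nominal
  size, which is this test's defining property. With min_cell ≥ 3 no cell is
  ever empty, so no continuity correction is applied to the log-ORs
  themselves; tables containing an empty cell yield a flagged, undefined
  result.

**Multiplicity.** Benjamini–Hochberg step-up over the pooled family of all
valid (pair, method) tests; the denominator is the number of tests actually
performed after cell filtering, not the number of reported rows, so a
reporting threshold does not distort the adjustment. Ties in p keep a stable
(snp_a, snp_b, method) order. Pairs whose SNPs have r² > 0.2 are then
removed as redundant; pairs with undefined r² are kept with a warning.

**Post-hoc genotypic test.** Logistic LRT of 8 joint-genotype indicators
(reference cell (0, 0)) plus covariates against covariates-only; cells
unobserved in the data drop their indicator, and the reported df shrinks
accordingly.

**Main-effect scan.** Per-SNP covariate-adjusted logistic regression with
additive coding on complete cases (a fixed-effects stand-in for mixed-model
association scans; relatedness structure is not modeled). Genomic inflation
is summarized as λ = median(χ²)/0.4549.

## Risk scores

* **Effect tables.** The OR of cell k is cell-vs-rest by default (the 2×2
  table of cell counts against the summed remainder); cell-vs-reference is
  available by flag. ORs are unadjusted for covariates. The MDR threshold T
  is the training data's overall case:control ratio. Interactions are
  de-duplicated by unordered pair identity before scoring.
* **ERS/PRS** average per-interaction (per-SNP) contributions over the
  interactions (SNPs) observed for each individual, so missing genotypes
  shrink the denominator rather than the score; individuals observing
  nothing get a missing score. Effect tables are always estimated on data
  disjoint from the scored samples, and scoring one individual depends only
  on that individual's genotypes and the frozen tables. Both scores are
  linear in their effect inputs, and adding zero-effect interactions shrinks
  ERS values (through N_j) without changing their ranking.
* **CRS** mixes PRS and ERS with a weight chosen by grid search (step 0.01)
  maximizing AUC on a selection dataset distinct from the evaluation
  dataset; ties resolve to the smallest w, so uninformative mixtures
  degenerate to the ERS endpoint deterministically. P-value tiers for ERS
  construction default to 1e-7 / 1e-6 / 1e-5.
* **Permutation selection.** Each interaction's MDR predictions are scored
  by balanced accuracy (the prediction metric is a package choice) on every
  test set; the null distribution permutes the prediction vector against the
  labels, realized as draws from the hypergeometric law that an exchangeable
  permutation induces on the correctly-labeled-case count — distributionally
  identical to explicit shuffling and far cheaper at 10,000 permutations.
  The add-one estimator p = (1 + #{null ≥ obs})/(1 + n_perm) avoids p = 0;
  selection requires p < α in every test set. Interactions whose test labels
  collapse to one class are skipped with a recorded reason.

## Survival and table statistics

Quantile groups are formed by stable rank with sizes differing by at most
one (no interpolation); fully tied scores still yield balanced groups, with
a warning. Kaplan–Meier and the k-group log-rank test are delegated to
`lifelines`; individuals without an observed onset contribute censored time
at their last-record age, and subjects with no valid age are excluded with a
logged count. AUC is the Mann–Whitney probability with ties counted one
half. The summary-based two-sample t-test defaults to the Welch variant
(pooled available); Fisher's exact test is two-sided by the
probability-mass-ordering convention, with p = 1 under a zero margin.
Pooling of (n, mean, SD) group summaries combines within-group sums of
squares with the between-group spread of means.

## Synthetic data

The generator emulates the measurable ingredients of an elderly case-control
genetic study: independent biallelic SNPs in HWE (MAFs uniform on a
configurable range), sex/age/batch covariates with optional logit-scale
effects, additive per-allele main effects, and pairwise interactions planted
through 3×3 penetrance tables. Liability is additive on the logit scale;
each planted pair contributes logit(p[g1, g2]) − baseline_logit, so
penetrance tables anchored at the cohort baseline contribute exactly their
cell log-odds offsets. Age at onset is exponential after age 60 with a rate
increasing in liability (coefficient 0.4, scale 15 years, administrative
censoring at 95); unaffected individuals are censored at their last-record
age. A single seed drives two documented streams (genotypes, phenotypes),
so phenotype re-draws never perturb genotypes, and SNPs carrying planted
effects are exempt from simulated missingness so effect recovery is not
confounded with missing-data handling.

What the generator deliberately lacks — and what passing tests therefore do
not establish about real data — includes LD between non-planted SNPs,
relatedness and population structure (except where a test plants structure
explicitly), genotyping error, imputation dosage uncertainty, and any
realistic onset-age distribution beyond the qualitative
higher-risk-earlier-onset ordering.

### Problem sizes in the test and acceptance runs

Chosen as the smallest designs at which the targeted properties are
statistically comfortable: null calibration uses 5000 valid pairs of 2000
samples (99% binomial band 0.042–0.058 around a 5% size); planted-signal
recovery uses 20 replicate studies of 4000 samples × 300 SNPs with two
allele-product interactions (per-product log-OR 0.6, planted MAF 0.35,
penetrance anchored at baseline 0.3 — corner cells then comfortably clear
the 18-cell count filter); the combined-score study uses 6000 samples split
into train/selection/evaluation thirds with twenty 0.25-log-OR main-effect
SNPs feeding the PRS; permutation behavior uses 1000 permutations, where the
minimal attainable p is 1/1001. The one-command demo uses 4000 samples × 300
SNPs so the planted pairs are recoverable from the discovery half of the
pipeline's 50/25/25 sample split.

## Known limitations

Exhaustive screening is O(m²) and sized for annotation-restricted SNP panels
(tens of thousands of pairs per second on one core), not for millions of
SNPs; there is no distributed mode. MDR is strictly pairwise (k = 2) and not
cross-validated. The CRS is a linear mixture only. The joint-effects
variance constants follow the package's own calibration-based choice and may
differ in small samples from other published variants of the statistic.
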