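# Methods

`ndscan` implements a candidate-gene association scan for longitudinal
smoking and nicotine-dependence (ND) phenotypes: SNP quality control,
a linear-mixed-model scan over every SNP × phenotype pair, and joint
permutation inference with family-wise (Westfall–Young min-p) and FDR
corrections. A synthetic-cohort generator emulates the study design so
the whole chain is testable without external data.

## Study design being emulated

The target design is a school-based prospective cohort: several hundred
adolescents (default 544) followed from age ~12.5 over up to 20
three-month data-collection cycles, with six phenotypes measured each
cycle — the number of cigarettes smoked in the past three months (a
heavily right-skewed count) and five continuous ND scores (mFTQ,
ICD-10, withdrawal, self-medication, ND/craving). Genotypes are
candidate-gene tag SNPs (default panel sizes in the hundreds across ~24
genes). Covariates are sex and a three-level ethnicity (French-Canadian
as reference, other-European, other/mixed).

## Synthetic cohort generator

### Genotypes

Non-injected SNPs are drawn under Hardy–Weinberg equilibrium at an MAF
sampled uniformly from `maf_range`. LD blocks use haplotype chain
copying: all SNPs in a block share one MAF; each haplotype allele
copies the previous SNP's allele with probability √r² and is redrawn
otherwise, so adjacent SNPs attain the target genotype r² (decaying
geometrically with in-block distance) and r² = 1 yields exact haplotype
copies. The generator can inject three QC-defect categories, labelled
in SNP metadata: monomorphic SNPs, SNPs with an exact count of missing
calls above the missingness ceiling, and SNPs sampled with a nonzero
inbreeding coefficient F (genotype probabilities p²+Fpq, 2pq(1−F),
q²+Fpq; default F=0.6, a strong heterozygote deficit that a per-group
exact test detects reliably at the default group sizes). Background
per-call missingness defaults to 1%.

### Phenotypes

The generating model mirrors the fitted model. For individual *i*,
cycle *c*, phenotype *p*:

y_icp = b0_p + b_age·age + b_age²·age² + b_sex·sex_i + ethnicity effect
        + Σ_s G_is·β_sp + u0_ip + u1_ip·(age − mean age) + e_icp

* Ages are `age_start + cycle·age_step` plus uniform jitter (±0.125 y
  by default) so the random-slope covariance is identifiable.
* Dropout is monotone (per-cycle hazard, default 2%): once an
  individual leaves, no later observations exist.
* Random intercepts `u0` are correlated across phenotypes and residuals
  `e` carry the same correlation matrix; random slopes `u1` are
  independent. Applying the target correlation to both the intercepts
  and the residuals (rather than the intercepts alone) makes the
  realized observation-level and person-level phenotype correlations
  track the requested matrix without attenuation by the
  within/between variance mix — with intercepts only, a 0.6 target
  realizes around 0.49–0.58 under the default variances.
* The default correlation target is a single-factor matrix with
  loadings (0.72, 0.90, 0.78, 0.82, 0.86, 0.70), giving pairwise
  correlations of ~0.50–0.77, the moderate-to-strong range typical of
  adolescent smoking/ND scores.
* The cigarette count is generated on the natural-log scale and
  inverted via `max(round(exp(y) − 1), 0)`, so the log-scale model
  fitted downstream is correctly specified up to integer rounding.
  Default dispersions (intercept SD 1.0, residual SD 0.7 on the log
  scale around a log-intercept of 2.6) give a median count near the
  low teens with a long right tail; matching any particular published
  IQR is explicitly not a goal.
* Missing causal genotypes contribute their expected dosage so planted
  effects are not distorted by missingness.
* Default variance components (intercept SD 1.0, slope SD 0.08,
  residual SD 0.7) are free parameters of the generator, not estimates
  from any dataset; the slope-to-intercept ratio is deliberately small
  because person-level heterogeneity dominates questionnaire scores.

### What the generator does not emulate

Questionnaire item-level structure, real haplotype backgrounds,
smoking-uptake dynamics (phenotypes are stationary around a smooth age
trend), genotyping batch effects, and informative dropout. Passing
tests therefore demonstrate the statistical machinery is correct under
the assumed model, not that the model captures every feature of real
cohort data.

### Engineered QC reference panel

`reference_qc_panel` builds a 394-SNP panel with known filter
outcomes: 3 monomorphic, 3 with 30% missing calls, 48 polymorphic with
MAF < 0.05, 19 in Hardy–Weinberg disequilibrium (F = 0.6) in ≥1 ethnic
group, and 321 clean. Each SNP is rejection-sampled until it fails
exactly its intended filters at the default thresholds, so the flag
counts are deterministic by construction: category counts 3/3/51/19
(monomorphic SNPs necessarily also fall below the MAF threshold), a
union of 73 exclusions, and 321 retained.

## Quality control

Order and boundary conventions:

1. **Sample call rate** (default ≥ 0.95 keeps; boundary keeps) is
   applied before any SNP filter.
2. **Monomorphism**: all non-missing calls identical.
3. **Missingness**: missing fraction strictly greater than 0.20 (the
   SNP call-rate threshold 0.80 expressed as missingness).
4. **MAF**: strictly below 0.05 excludes; exactly 0.05 is retained.
5. **HWE**: exact conditional test (probability-ordering two-sided),
   run separately in each ethnic group on that group's non-missing
   calls; failure at α = 0.01 in ≥1 group excludes. The exact test is
   used because per-group counts can be small; α is configurable.
   Individuals with missing ethnicity are left out of HWE testing.

A SNP may fail several filters; the exclusion is the union and the
report retains the overlapping per-category flags. Filtering an
already-filtered matrix excludes nothing.

**Codings.** Additive coding counts minor-allele copies (0/1/2), with
the minor allele determined on the analysed sample (alt declared minor
at frequency exactly 0.5, a deterministic tie-break). When the
minor-homozygote count is ≤ 15 (inclusive), the SNP is recoded to a
dominant carrier contrast — the standard sparse-cell motivation; a
configurable variant applies the rule to any genotype category.

## Linear mixed model

For each SNP × phenotype pair: fixed effects are the coded SNP, sex,
two ethnicity contrasts (reference French-Canadian, the largest
group), and centered age with linear and quadratic terms; random
effects are a per-individual intercept and linear age slope with
unstructured 2×2 covariance; residuals are independent and
homoscedastic. The count phenotype enters as ln(count+1) (the unit
offset handles zeros; configurable). Age is centered at the analysed
sample mean, which improves conditioning and affects only the
intercept, not the SNP coefficient.

**Missing data.** Observation-level deletion for missing phenotype or
age; individual-level deletion for missing sex, ethnicity or genotype
(time-invariant quantities). Fits require ≥ 30 individuals (floor
configurable). Nuisance columns that are constant in the analysed
subset are dropped to keep the design full rank.

**Estimation.** REML by default (ML available). The implementation
profiles out the fixed effects and residual variance in closed form
and optimizes only the scaled Cholesky factor of the random-effect
covariance (log-diagonal parameterisation, 3 parameters), with every
per-cluster quantity reduced to 2×2 algebra via the Woodbury identity
on per-cluster sufficient statistics. Nelder–Mead with two fallback
starting points; optimizer tolerances xatol 1e-6 / fatol 1e-9. A fit
costs milliseconds, which is what makes the 1,926-model scan and
permutation refitting tractable; within a scan, each fit warm-starts
from the previous SNP's optimum (this changes no optimum, only the
iteration count). The solver is validated against statsmodels MixedLM
(agreement in β to ~1e-6 and SE to ~1e-3 relative on test fixtures)
and against OLS in the degenerate no-random-effects configuration.

**Fallback ladder** for non-convergence: restart from a dispersed
starting point, then drop the random slope (status
`ok_intercept_only`), else the fit is flagged `failed` with no
p-value; failures remain rows of the scan table. Inference on the SNP
coefficient is a Wald z test (normal approximation rather than
Satterthwaite degrees of freedom): the permutation layer, not the
asymptotic p-value, carries the final inference.

**Nominal significance** is raw p < 0.01, feeding the hit table and
the per-phenotype presence/absence grid.

## Permutation inference

The permutation unit is the individual: each permutation reassigns
every individual's full genotype vector to another individual's
complete phenotype-and-covariate history. Covariates stay attached to
the phenotype side — any other choice would break the
phenotype–covariate dependence the scheme is designed to preserve.
Only the genotype–phenotype link is broken; LD, phenotype
correlations and the repeated-measures structure are intact. Each
permutation refits the identical model specification (same codings,
same fallback ladder), so the identity permutation reproduces the
observed scan bit for bit.

* **Permutation p-values**: add-one convention
  (1 + #{b: p_b ≤ p_obs})/(B+1) in Monte-Carlo mode; in exhaustive
  mode (all n! bijections, identity included) the plain proportion is
  the exact permutation p. Comparisons use inclusive ≤ on the p scale,
  making "smaller is more extreme" uniform across tests that mix
  codings and phenotype scales — which is also why the family-wise
  procedure uses the min-p form of Westfall–Young rather than a
  statistic-scale maxT.
* **Westfall–Young min-p**: the per-permutation family minimum of the
  null p-values; adjusted p-values are tail probabilities of that
  minimum and dominate the per-test permutation p by construction.
  α* — the raw-p threshold controlling FWER — is the empirical
  `fwer_alpha` quantile of the family-minimum distribution (linear
  interpolation); a warning is recorded when B·fwer_alpha < 1. For
  independent tests α* approaches the Šidák value 1−(1−α)^(1/T).
* **FDR**: Benjamini–Hochberg step-up applied across the full test
  family (all scan rows, not only nominal hits), separately to raw
  and permutation p-values. Applying FDR across all tests rather than
  per phenotype matches a hit table that mixes phenotypes in a single
  FDR column.
* **Budget**: B defaults to 1,000 (CLI `--permutations`); production
  analyses of this design historically used B on the order of 10⁵,
  which is not needed for desk-scale validation.

For fast calibration experiments the package also exposes the
degenerate single-observation, no-covariate case of the scan model
(`marginal_scan_pvalue_function`), for which the mixed model collapses
to simple linear regression and the whole B×T null matrix is
vectorised.

## Validation experiments and problem sizes

The test suite validates the chain at sizes chosen to give tight Monte
Carlo error while keeping the default run short:

* Scan cardinality: the engineered panel at n = 150 with 6 cycles →
  exactly 321 × 6 = 1,926 scan rows.
* QC: the engineered panel yields 73/321 with category counts
  3/3/51/19 at both n = 150 and n = 544.
* Wald type-I error: 500 global-null cohorts (n = 120, 4 cycles),
  rejection at α = 0.05 within 0.05 ± 0.02.
* Permutation super-uniformity: 400 replicates, B = 199, degenerate
  scan model; P(p ≤ α) ≤ α + Monte-Carlo error at α ∈ {0.01, 0.05, 0.1}.
* FWER: 200 replicates of a 50-test global-null family (n = 100,
  B = 2,000): family-wise error within 0.05 ± 0.03 and mean α* within
  1e-4 of the Šidák limit 1 − 0.95^(1/50) ≈ 0.001025.
* Oracles: exhaustive 120-permutation p equals an independent
  brute-force refit loop exactly (n = 5); BH-FDR matches hand-computed
  step-up vectors; the HWE exact test matches a rational-arithmetic
  enumeration to 1e-12 for totals ≤ 100.
* Parameter recovery: 100 replicates at n = 500 with 8 cycles and a
  planted additive effect of 0.5 → |bias| < 0.05 and ~95% Wald
  coverage.

## Numerical choices and degenerate inputs

* HWE exact test: log-gamma evaluation of the conditional
  distribution; configurations are included in the tail when their
  probability is ≤ the observed probability times (1 + 1e-12), which
  makes probability ties robust to floating-point rounding.
  Monomorphic input returns 1.0 (monomorphism has its own filter).
* MAF of an all-missing vector is an error; an all-missing SNP cannot
  be encoded.
* LD r² is undefined (NaN) when either SNP is constant on the shared
  non-missing support.
* Cohort summary quantiles use linear interpolation (IQR = Q3 − Q1).
* Phenotype correlations default to per-individual means across cycles
  (avoiding within-person pseudo-replication); an observation-level
  variant is available. Count phenotypes are put on the log scale
  first.
* Non-PSD phenotype-correlation targets are rejected before any
  sampling; the matrix square root clips eigenvalues at 0 within
  tolerance.

## Known limitations

* Wald z (not t/Satterthwaite) for the raw p-values; mildly
  anticonservative at small n, by design secondary to the permutation
  inference.
* The permutation engine refits every model per permutation; at the
  full 1,926-test scale a large B is a compute-cluster job, not a
  desktop one. The engine is deliberately serial and seed-driven so
  results never depend on scheduling.
* The LD generator controls adjacent-pair r² within blocks only;
  arbitrary LD matrices are out of scope.
* Dominant recodings depend on the analysed sample's genotype counts,
  so coding can differ between cohorts of different size — as the
  sparse-cell rule intends.
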