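# ndscan

Candidate-gene association analysis for longitudinal smoking and
nicotine-dependence (ND) phenotypes in adolescent cohorts.

The scientific setting: several hundred novice adolescent smokers are
followed over up to 20 quarterly data-collection cycles, with six
repeated phenotypes — the number of cigarettes smoked in the past
three months and five questionnaire-derived ND scores (mFTQ, ICD-10,
withdrawal, self-medication, ND/craving) — and a few hundred candidate-
gene tag SNPs. The analytical question is which SNPs are associated
with which phenotypes, with honest inference despite strongly
correlated phenotypes, LD between SNPs, and repeated measures within
individuals.

`ndscan` implements the full chain:

1. **SNP/sample QC** — sample call rate ≥ 0.95, then SNP filters for
   monomorphism, > 20% missingness, MAF < 0.05, and an exact
   Hardy–Weinberg test per ethnic group (α = 0.01, failure in ≥ 1 group
   excludes); additive minor-allele-dosage coding, recoded to a
   dominant carrier contrast when the minor-homozygote count is ≤ 15.
2. **Linear mixed model scan** — for each SNP × phenotype pair,

   `y = β₀ + β_g·g + β_sex·sex + ethnicity + β₁·age_c + β₂·age_c² + u₀ + u₁·age_c + ε`

   with per-individual random intercept u₀ and random age slope u₁
   (unstructured 2×2 covariance), REML estimation, Wald z test for
   β_g; the cigarette count is analysed as ln(count + 1).
3. **Joint permutation inference** — permutations reassign whole
   genotype vectors across individuals' complete phenotype/covariate
   histories, preserving LD, phenotype correlation and the repeated-
   measures structure; corrections are per-test permutation p-values,
   Westfall–Young family-wise adjustment in min-p form (with the
   family-wise raw-p threshold α*), and Benjamini–Hochberg FDR on both
   raw and permutation p-values.
4. **Synthetic cohorts** — a first-class generator emulating the
   design (LD blocks, injectable QC defects, correlated phenotypes,
   planted additive effects, monotone dropout), so the whole pipeline
   is testable end to end with no external data.

See `docs/methods.md` for the model, conventions and validation
experiments in detail.

## Worked example

```python
import ndscan as nd

design  = nd.CohortDesign(n_individuals=200, n_cycles=5, dropout_rate=0.02)
spec    = nd.SnpSpec(n_snps=8, ld_blocks=[(2, 0.98)])
effects = nd.EffectSpec(causal_effects={
    "snp_0006": {"nd_craving": 0.9, "self_medication": 0.45}})
genotypes, panel, covariates = nd.simulate_cohort(design, spec, effects, seed=1)

retained, qc_report = nd.filter_snps(genotypes, covariates)
codings = nd.encode_all(retained)
scan    = nd.run_scan(retained, panel, covariates, codings=codings)

fit  = nd.scan_pvalue_function(retained, panel, covariates, codings=codings)
null = nd.permutation_null(fit, retained.n_samples, n_permutations=99, seed=1)
adjusted = nd.assemble_adjusted(scan, null)
```

Output (a few minutes; every permutation refits all 48 models):

```
QC: 0 of 8 SNPs excluded, 8 retained
scan: 48 SNP x phenotype models, 2 nominal hits (p < 0.01)
  gene   snp_id       phenotype    beta         p  p_perm   fdr_raw  fdr_perm  p_maxt
GENE07 snp_0006      nd_craving  0.6893 1.694e-11    0.01 8.133e-10      0.24    0.01
GENE07 snp_0006 self_medication  0.3179  0.001687    0.01   0.04049      0.24    0.06
GENE06 snp_0005      withdrawal -0.3934   0.01178    0.02    0.1884    0.2667    0.38
maxT family-wise raw-p threshold alpha* = 0.0019
```

Reading this: the planted SNP is recovered as the top association on
both target phenotypes (`beta` is its effect on the analysis scale,
`p` the raw mixed-model Wald p). With only B = 99 permutations the
permutation p cannot go below 1/(B+1) = 0.01, and the FDR of the
permutation p-values is floored accordingly — with a production-scale
B these columns sharpen. `p_maxt` is the family-wise adjusted p, and
α* is the raw-p threshold that controls the family-wise error rate at
0.05 for this 48-test family.

A shell interface wraps the same pipeline:

```bash
ndscan simulate --out-dir cohort --seed 1 --individuals 200 --cycles 5 --snps 8
ndscan qc   --genotypes cohort/genotypes.tsv --covariates cohort/covariates.csv --out-dir qc
ndscan scan --genotypes qc/genotypes_qc.tsv --phenotypes cohort/phenotypes.csv --out scan.tsv
ndscan permute --genotypes qc/genotypes_qc.tsv --phenotypes cohort/phenotypes.csv \
       --permutations 99 --seed 1 --out null.tsv
ndscan adjust --scan scan.tsv --null null.tsv --out adjusted.tsv
ndscan report --scan adjusted.tsv --genotypes qc/genotypes_qc.tsv --out-dir report
```

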