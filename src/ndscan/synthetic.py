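"""Synthetic cohort generator.

Emulates the statistical structure of a longitudinal school-based
smoking cohort: several hundred adolescents followed over up to 20
three-month data-collection cycles, six strongly inter-correlated
phenotypes (one cigarette count, five nicotine-dependence scores), and
candidate-gene SNP genotypes with LD blocks, realistic minor-allele
frequencies and injectable QC defects (monomorphic SNPs, high
missingness, Hardy-Weinberg violations).

The phenotype generator mirrors the model fitted downstream: for
individual *i*, cycle *c* and phenotype *p*,

    y_icp = b0_p + b_age * age_ic + b_age2 * age_ic^2 + b_sex * sex_i
            + ethnicity effects + sum_s G_is * beta_sp
            + u0_ip + u1_ip * (age_ic - mean age) + e_icp

with per-individual random intercepts ``u0`` correlated across
phenotypes (a shared-factor construction targeting the requested 6x6
phenotype correlation matrix), independent random age slopes ``u1``,
and independent residuals.  The count phenotype is generated on the
natural-log scale and inverted via ``round(exp(y) - 1)``, so the
log-scale linear mixed model fitted by the analysis layer is (up to
rounding) correctly specified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    COUNT_PHENOTYPES,
    ETHNICITIES,
    MISSING,
    PHENOTYPES,
    GenotypeMatrix,
    PhenotypePanel,
)

__all__ = [
    "CohortDesign",
    "SnpSpec",
    "EffectSpec",
    "simulate_individuals",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "reference_qc_panel",
    "default_phenotype_correlation",
]


# --------------------------------------------------------------------------
# design specifications
# --------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Cohort layout: who is observed, when, and for how long.

    Defaults mirror the emulated study: 544 genotyped ever-smokers from
    a cohort recruited at age 12-13 and followed over 20 quarterly
    cycles, 41% male, with French-Canadian / other-European / other
    ethnicity mix.
    """

    n_individuals: int = 544
    n_cycles: int = 20
    age_start: float = 12.5
    age_step: float = 0.25
    dropout_rate: float = 0.02
    sex_fraction: float = 0.41
    ethnicity_probs: tuple[float, float, float] = (0.35, 0.41, 0.24)
    #: Half-width of the uniform jitter added to each observation age so
    #: the random-slope covariance is identifiable.
    age_jitter: float = 0.125

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if self.n_cycles < 2:
            raise ValueError("n_cycles must be at least 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        probs = np.asarray(self.ethnicity_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0):
            raise ValueError("ethnicity_probs must be three non-negative values")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("ethnicity_probs must sum to 1 within 1e-9")


@dataclass
class SnpSpec:
    """Composition of the simulated SNP panel.

    ``ld_blocks`` is a list of ``(size, target_r2)`` pairs; each block
    occupies consecutive SNPs sharing one minor-allele frequency, with
    adjacent SNPs reaching the target genotype r^2 via haplotype
    copying.  The three ``n_*`` defect counts inject SNPs that the QC
    stage is expected to remove.
    """

    n_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)
    n_monomorphic: int = 0
    n_high_missing: int = 0
    missing_fraction_high: float = 0.30
    n_hwe_violating: int = 0
    hwe_inbreeding_coefficient: float = 0.6
    #: Background per-call missingness applied to all non-injected SNPs.
    missing_rate: float = 0.01
    n_genes: int = 24

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        n_injected = self.n_monomorphic + self.n_high_missing + self.n_hwe_violating
        if n_injected > self.n_snps:
            raise ValueError("injected defect counts exceed n_snps")
        block_total = sum(size for size, _ in self.ld_blocks)
        if block_total > self.n_snps - n_injected:
            raise ValueError("LD block sizes exceed available SNPs")
        for i, (size, r2) in enumerate(self.ld_blocks):
            if size < 2:
                raise ValueError(f"LD block {i} must contain at least 2 SNPs")
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"LD block {i} target r^2 must lie in [0, 1]")
        if not -1.0 < self.hwe_inbreeding_coefficient < 1.0:
            raise ValueError("hwe_inbreeding_coefficient must lie in (-1, 1)")
        if not 0.0 <= self.missing_fraction_high <= 1.0:
            raise ValueError("missing_fraction_high must lie in [0, 1]")


def default_phenotype_correlation() -> np.ndarray:
    """Single-factor 6x6 phenotype correlation with off-diagonals ~0.5-0.8.

    Loadings are chosen so the pairwise correlations fall in the
    moderate-to-strong range reported for adolescent smoking/ND scores
    (roughly 0.47-0.83).  The construction ``R = ll' + diag(1 - l^2)``
    is positive definite for loadings in (0, 1).
    """
    loadings = np.array([0.72, 0.90, 0.78, 0.82, 0.86, 0.70])
    corr = np.outer(loadings, loadings)
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class EffectSpec:
    """Generating model for phenotypes.

    ``causal_effects`` maps SNP id -> {phenotype -> additive effect per
    minor-allele copy, on the analysis scale (log scale for the count
    phenotype)}.  Dispersion parameters accept a scalar (shared across
    phenotypes) or a length-6 sequence.
    """

    causal_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    phenotype_correlation: np.ndarray = field(
        default_factory=default_phenotype_correlation
    )
    intercepts: tuple[float, ...] = (2.6, 9.3, 1.0, 2.0, 1.0, 2.0)
    age_linear: float = 0.15
    age_quadratic: float = -0.01
    sex_effect: float = 0.2
    #: Effects for the two non-reference ethnicity categories
    #: (european, other) relative to french_canadian.
    ethnicity_effects: tuple[float, float] = (0.1, -0.1)
    random_intercept_sd: float | Sequence[float] = 1.0
    random_slope_sd: float | Sequence[float] = 0.08
    residual_sd: float | Sequence[float] = 0.7

    def __post_init__(self) -> None:
        R = np.asarray(self.phenotype_correlation, dtype=float)
        k = len(PHENOTYPES)
        if R.shape != (k, k):
            raise ValueError(f"phenotype_correlation must be {k}x{k}")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("phenotype_correlation must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ValueError("phenotype_correlation must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-9:
            raise ValueError("phenotype_correlation is not positive semi-definite")
        self.phenotype_correlation = R
        for name in ("random_intercept_sd", "random_slope_sd", "residual_sd"):
            value = np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), (k,)
            ).copy()
            if np.any(value < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, value)


def _correlation_factor(corr: np.ndarray) -> np.ndarray:
    """Square root of a (possibly singular) correlation matrix via the
    eigendecomposition; tiny negative eigenvalues are clipped."""
    w, v = np.linalg.eigh(corr)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


# --------------------------------------------------------------------------
# individuals and covariates
# --------------------------------------------------------------------------

def simulate_individuals(design: CohortDesign, seed: int) -> pd.DataFrame:
    """Draw per-individual covariates (sex, ethnicity)."""
    rng = np.random.default_rng(seed)
    n = design.n_individuals
    ids = [f"ind_{i:04d}" for i in range(n)]
    sex = (rng.random(n) < design.sex_fraction).astype(int)
    ethnicity = rng.choice(ETHNICITIES, size=n, p=design.ethnicity_probs)
    return pd.DataFrame({"id": ids, "sex": sex, "ethnicity": ethnicity})


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

def _hwe_genotypes(rng: np.random.Generator, maf: float, n: int) -> np.ndarray:
    """Draw n genotypes (minor-allele copies) under Hardy-Weinberg."""
    h1 = rng.random(n) < maf
    h2 = rng.random(n) < maf
    return (h1.astype(np.int8) + h2.astype(np.int8))


def _inbred_genotypes(
    rng: np.random.Generator, maf: float, f: float, n: int
) -> np.ndarray:
    """Genotypes with inbreeding coefficient ``f`` (heterozygote deficit
    for f > 0, excess for f < 0)."""
    p, q = maf, 1.0 - maf
    probs = np.array(
        [q * q + f * p * q, 2 * p * q * (1 - f), p * p + f * p * q]
    )
    if np.any(probs < -1e-12):
        raise ValueError(
            f"inbreeding coefficient {f} infeasible at MAF {maf:.3f}"
        )
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    return rng.choice(np.array([0, 1, 2], dtype=np.int8), size=n, p=probs)


def _block_genotypes(
    rng: np.random.Generator, maf: float, r2: float, size: int, n: int
) -> np.ndarray:
    """LD block via haplotype chain copying.

    All SNPs in the block share one MAF.  Each haplotype allele at SNP
    j copies the allele at SNP j-1 with probability ``sqrt(r2)`` and is
    otherwise redrawn, so adjacent SNPs have haplotype correlation
    sqrt(r2) and genotype r^2 equal to the target; r^2 decays
    geometrically with distance inside the block.  At r2 = 1 haplotypes
    are exact copies.
    """
    c = math.sqrt(r2)
    haps = np.empty((2, size, n), dtype=np.int8)
    for h in range(2):
        haps[h, 0] = rng.random(n) < maf
        for j in range(1, size):
            copy = rng.random(n) < c
            fresh = (rng.random(n) < maf).astype(np.int8)
            haps[h, j] = np.where(copy, haps[h, j - 1], fresh)
    return haps[0] + haps[1]


def simulate_genotypes(
    design: CohortDesign, spec: SnpSpec, seed: int
) -> GenotypeMatrix:
    """Simulate the SNP panel for ``design.n_individuals`` individuals.

    Layout (row order): injected monomorphic SNPs, injected high-missing
    SNPs, injected HWE-violating SNPs, LD blocks, then independent
    Hardy-Weinberg SNPs.  Injected categories are labelled in the
    ``injected`` metadata column.
    """
    rng = np.random.default_rng(seed)
    n = design.n_individuals
    m = spec.n_snps
    geno = np.empty((m, n), dtype=np.int8)
    injected = ["none"] * m
    lo, hi = spec.maf_range

    row = 0
    for _ in range(spec.n_monomorphic):
        geno[row] = 0
        injected[row] = "monomorphic"
        row += 1
    high_missing_rows = []
    for _ in range(spec.n_high_missing):
        geno[row] = _hwe_genotypes(rng, rng.uniform(lo, hi), n)
        injected[row] = "high_missing"
        high_missing_rows.append(row)
        row += 1
    for _ in range(spec.n_hwe_violating):
        geno[row] = _inbred_genotypes(
            rng, rng.uniform(lo, hi), spec.hwe_inbreeding_coefficient, n
        )
        injected[row] = "hwe_violating"
        row += 1
    for b, (size, r2) in enumerate(spec.ld_blocks):
        maf = rng.uniform(lo, hi)
        try:
            block = _block_genotypes(rng, maf, r2, size, n)
        except ValueError as exc:  # pragma: no cover - defensive
            raise ValueError(f"LD block {b} is infeasible: {exc}") from exc
        geno[row : row + size] = block
        for j in range(size):
            injected[row + j] = f"ld_block_{b}"
        row += size
    while row < m:
        geno[row] = _hwe_genotypes(rng, rng.uniform(lo, hi), n)
        row += 1

    # background missingness everywhere, exact-count missingness for the
    # injected high-missing SNPs (guarantees the >20% flag fires)
    if spec.missing_rate > 0:
        mask = rng.random((m, n)) < spec.missing_rate
        geno[mask] = MISSING
    n_miss = int(round(spec.missing_fraction_high * n))
    for r in high_missing_rows:
        cols = rng.choice(n, size=n_miss, replace=False)
        geno[r, cols] = MISSING

    per_gene = max(1, math.ceil(m / spec.n_genes))
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp_{i:04d}" for i in range(m)],
            "gene": [f"GENE{i // per_gene + 1:02d}" for i in range(m)],
            "chrom": "1",
            "pos": [1000 * (i + 1) for i in range(m)],
            "ref": "A",
            "alt": "G",
            "injected": injected,
        }
    )
    samples = [f"ind_{i:04d}" for i in range(n)]
    return GenotypeMatrix(genotypes=geno, snps=snps, samples=samples)


# --------------------------------------------------------------------------
# phenotypes
# --------------------------------------------------------------------------

def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    design: CohortDesign,
    effects: EffectSpec,
    seed: int,
) -> PhenotypePanel:
    """Generate the longitudinal phenotype panel.

    Dropout is monotone: an individual observed at cycle ``t`` was
    observed at every earlier cycle.  Missing causal genotypes
    contribute their expected dosage so the planted effect is not
    distorted by missingness.
    """
    rng = np.random.default_rng(seed)
    n = design.n_individuals
    k = len(PHENOTYPES)
    if list(covariates["id"]) != list(genotypes.samples):
        raise ValueError("covariates and genotypes must cover the same individuals")
    for snp_id in effects.causal_effects:
        if snp_id not in set(genotypes.snps["snp_id"]):
            raise ValueError(f"causal SNP {snp_id!r} not present in genotypes")

    # retention: once out, out
    if design.dropout_rate > 0:
        drop = rng.random((n, design.n_cycles - 1)) < design.dropout_rate
        stays = np.concatenate(
            [np.ones((n, 1), dtype=bool), ~np.maximum.accumulate(drop, axis=1)],
            axis=1,
        )
    else:
        stays = np.ones((n, design.n_cycles), dtype=bool)

    cycles = np.arange(design.n_cycles)
    base_age = design.age_start + cycles * design.age_step
    ages = np.tile(base_age, (n, 1))
    if design.age_jitter > 0:
        ages = ages + rng.uniform(
            -design.age_jitter, design.age_jitter, size=ages.shape
        )

    # random effects; the target cross-phenotype correlation is applied
    # to the random intercepts and to the residuals (slopes independent),
    # so the observation- and person-level phenotype correlations both
    # track the requested matrix
    C = _correlation_factor(effects.phenotype_correlation)
    u0 = (rng.standard_normal((n, k)) @ C.T) * effects.random_intercept_sd
    u1 = rng.normal(0.0, 1.0, size=(n, k)) * effects.random_slope_sd

    # per-individual genetic contribution on each phenotype scale
    genetic = np.zeros((n, k))
    for snp_id, per_pheno in effects.causal_effects.items():
        g = genotypes.vector(snp_id).astype(float)
        observed = g != MISSING
        if observed.any():
            g[~observed] = g[observed].mean()
        else:
            g[:] = 0.0
        for pheno, beta in per_pheno.items():
            genetic[:, PHENOTYPES.index(pheno)] += beta * g

    sex = covariates["sex"].to_numpy(dtype=float)
    eth = covariates["ethnicity"].to_numpy()
    eth_effect = np.zeros(n)
    eth_effect[eth == ETHNICITIES[1]] = effects.ethnicity_effects[0]
    eth_effect[eth == ETHNICITIES[2]] = effects.ethnicity_effects[1]

    mean_age = ages[stays].mean()
    rows: list[dict] = []
    resid = (
        rng.standard_normal((n, design.n_cycles, k)) @ C.T
    ) * effects.residual_sd
    intercepts = np.asarray(effects.intercepts, dtype=float)
    for i in range(n):
        for c in range(design.n_cycles):
            if not stays[i, c]:
                break
            age = ages[i, c]
            fixed = (
                intercepts
                + effects.age_linear * age
                + effects.age_quadratic * age * age
                + effects.sex_effect * sex[i]
                + eth_effect[i]
                + genetic[i]
            )
            y = fixed + u0[i] + u1[i] * (age - mean_age) + resid[i, c]
            record = {"id": covariates["id"].iloc[i], "cycle": c, "age": age}
            for p, name in enumerate(PHENOTYPES):
                if name in COUNT_PHENOTYPES:
                    record[name] = max(int(round(math.expm1(y[p]))), 0)
                else:
                    record[name] = y[p]
            rows.append(record)
    obs = pd.DataFrame(rows)
    return PhenotypePanel(observations=obs)


def simulate_cohort(
    design: CohortDesign,
    spec: SnpSpec,
    effects: EffectSpec,
    seed: int,
) -> tuple[GenotypeMatrix, PhenotypePanel, pd.DataFrame]:
    """Full cohort: covariates, genotypes and phenotype panel.

    Child seeds are derived deterministically from ``seed`` so the
    output is bit-reproducible.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    covariates = simulate_individuals(design, ss[0].generate_state(1)[0] % 2**31)
    genotypes = simulate_genotypes(design, spec, ss[1].generate_state(1)[0] % 2**31)
    panel = simulate_phenotypes(
        genotypes, covariates, design, effects, ss[2].generate_state(1)[0] % 2**31
    )
    return genotypes, panel, covariates


# --------------------------------------------------------------------------
# engineered QC reference panel
# --------------------------------------------------------------------------

def reference_qc_panel(
    n_individuals: int = 544, seed: int = 0
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Engineered 394-SNP panel with known QC outcomes.

    Construction (all counts by rejection sampling against the default
    QC thresholds, so each SNP fails exactly its intended filters):

    * 3 monomorphic SNPs (necessarily also below the MAF threshold),
    * 3 SNPs with 30% missing calls and otherwise clean genotypes,
    * 48 polymorphic SNPs with MAF strictly below 0.05,
    * 19 SNPs violating Hardy-Weinberg equilibrium (inbreeding
      coefficient 0.6) in at least one ethnic group,
    * 321 clean SNPs passing every filter.

    The defect categories overlap only where forced by definition
    (monomorphic implies MAF < 0.05), so the union of flagged SNPs is
    73 and 321 SNPs survive QC.
    """
    from . import qc

    thresholds = qc.QcThresholds()
    design = CohortDesign(n_individuals=n_individuals)
    rng = np.random.default_rng(seed)
    covariates = simulate_individuals(design, rng.integers(2**31))
    eth = covariates["ethnicity"].to_numpy()
    groups = [np.flatnonzero(eth == e) for e in ETHNICITIES]
    n = n_individuals

    def hwe_status(g: np.ndarray) -> list[bool]:
        """Per-group HWE rejection at the configured alpha."""
        fails = []
        for idx in groups:
            sub = g[idx]
            sub = sub[sub != MISSING]
            counts = [(sub == v).sum() for v in (0, 1, 2)]
            p = qc.hwe_exact_test(*counts)
            fails.append(p < thresholds.hwe_alpha)
        return fails

    def observed_maf(g: np.ndarray) -> float:
        sub = g[g != MISSING]
        return qc.compute_maf(sub) if len(sub) else 0.0

    def with_background_missing(g: np.ndarray) -> np.ndarray:
        g = g.copy()
        g[rng.random(n) < 0.01] = MISSING
        return g

    def rejection_sample(category: str) -> np.ndarray:
        for _ in range(1000):
            if category == "clean":
                g = with_background_missing(
                    _hwe_genotypes(rng, rng.uniform(0.10, 0.45), n)
                )
                if (
                    observed_maf(g) >= thresholds.maf_min
                    and not any(hwe_status(g))
                    and (g == MISSING).mean() <= thresholds.snp_missing_max
                ):
                    return g
            elif category == "low_maf":
                g = with_background_missing(
                    _hwe_genotypes(rng, rng.uniform(0.01, 0.04), n)
                )
                maf = observed_maf(g)
                if 0.0 < maf < thresholds.maf_min and not any(hwe_status(g)):
                    return g
            elif category == "high_missing":
                g = _hwe_genotypes(rng, rng.uniform(0.10, 0.45), n)
                cols = rng.choice(n, size=int(round(0.30 * n)), replace=False)
                g = g.copy()
                g[cols] = MISSING
                if observed_maf(g) >= thresholds.maf_min and not any(hwe_status(g)):
                    return g
            elif category == "hwe_violating":
                g = with_background_missing(
                    _inbred_genotypes(rng, rng.uniform(0.15, 0.45), 0.6, n)
                )
                if (
                    observed_maf(g) >= thresholds.maf_min
                    and any(hwe_status(g))
                    and (g == MISSING).mean() <= thresholds.snp_missing_max
                ):
                    return g
            else:
                raise ValueError(category)
        raise RuntimeError(f"could not realize a {category!r} SNP in 1000 draws")

    composition = (
        [("monomorphic", 3), ("high_missing", 3), ("low_maf", 48),
         ("hwe_violating", 19), ("clean", 321)]
    )
    rows, labels = [], []
    for category, count in composition:
        for _ in range(count):
            if category == "monomorphic":
                g = with_background_missing(np.zeros(n, dtype=np.int8))
            else:
                g = rejection_sample(category)
            rows.append(g)
            labels.append(category)

    order = rng.permutation(len(rows))
    geno = np.asarray(rows, dtype=np.int8)[order]
    labels = [labels[i] for i in order]
    m = len(rows)
    per_gene = math.ceil(m / 24)
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp_{i:04d}" for i in range(m)],
            "gene": [f"GENE{i // per_gene + 1:02d}" for i in range(m)],
            "chrom": "1",
            "pos": [1000 * (i + 1) for i in range(m)],
            "ref": "A",
            "alt": "G",
            "injected": labels,
        }
    )
    gm = GenotypeMatrix(genotypes=geno, snps=snps, samples=list(covariates["id"]))
    return gm, covariates
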