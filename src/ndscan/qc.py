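"""Genotype quality control and analysis codings.

Filters follow the usual candidate-gene pipeline: sample call rate
first, then per-SNP filters for monomorphism, excess missingness, low
minor-allele frequency and Hardy-Weinberg disequilibrium tested
separately within each ethnic group.  A SNP may fail several filters;
the exclusion is the union, and the report keeps both the overlapping
per-category flags and the union count.

Boundary conventions (each read literally from the filter definitions
and applied consistently): a call rate exactly at the threshold keeps;
MAF exactly at the threshold keeps (the rule is strict ``< maf_min``);
a minor-homozygote count exactly at the recode threshold switches to
the dominant coding (the rule is inclusive ``<= 15``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import ETHNICITIES, MISSING, GenotypeMatrix

__all__ = [
    "QcThresholds",
    "QCReport",
    "CodedGenotype",
    "compute_maf",
    "hwe_exact_test",
    "filter_samples",
    "filter_snps",
    "encode_genotype",
    "encode_all",
]


@dataclass
class QcThresholds:
    """Filter thresholds; defaults match the emulated study design."""

    sample_call_rate_min: float = 0.95
    snp_call_rate_min: float = 0.80
    snp_missing_max: float = 0.20
    maf_min: float = 0.05
    hwe_alpha: float = 0.01
    hwe_groups: tuple[str, ...] = ETHNICITIES

    def __post_init__(self) -> None:
        for name in ("sample_call_rate_min", "snp_call_rate_min",
                     "snp_missing_max", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.hwe_alpha < 1.0:
            raise ValueError("hwe_alpha must lie in (0, 1)")


@dataclass
class QCReport:
    """Outcome of the SNP filters.

    ``per_snp`` has one row per input SNP with boolean flag columns
    (``monomorphic``, ``high_missing``, ``low_maf``, ``hwe_fail``), a
    per-group HWE detail column and the final decision.  Category counts
    overlap; ``excluded_union`` counts SNPs with at least one flag.
    """

    per_snp: pd.DataFrame
    category_counts: dict[str, int]
    excluded_union: int
    retained_snp_ids: list[str]
    sample_call_rates: pd.Series
    excluded_samples: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_input_snps": len(self.per_snp),
            "excluded_union": self.excluded_union,
            "n_retained": len(self.retained_snp_ids),
            "category_counts": dict(self.category_counts),
            "n_excluded_samples": len(self.excluded_samples),
        }


@dataclass
class CodedGenotype:
    """Analysis-ready numeric coding for one SNP.

    Additive coding counts copies of the minor allele (0/1/2); dominant
    coding contrasts carriers of the minor allele (1) against major
    homozygotes (0).  Missing calls are NaN.
    """

    snp_id: str
    coding: str  # "additive" | "dominant"
    values: np.ndarray  # float vector, NaN for missing
    minor_allele: str
    major_allele: str
    maf: float
    #: Individual ids aligned with ``values`` (None when unknown).
    samples: list[str] | None = None


def compute_maf(genotypes: np.ndarray) -> float:
    """Minor-allele frequency of a 0/1/2 genotype vector.

    Missing calls (:data:`MISSING`) are ignored.  The counted (alt)
    allele is declared minor when its frequency is <= 0.5, which fixes
    the tie-break at frequency exactly 0.5 deterministically.
    """
    g = np.asarray(genotypes)
    g = g[g != MISSING]
    if g.size == 0:
        raise ValueError("cannot compute MAF of an all-missing vector")
    f_alt = g.sum() / (2.0 * g.size)
    return float(min(f_alt, 1.0 - f_alt))


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional test for Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts whose conditional probability does not
    exceed that of the observed configuration (two-sided, by
    probability ordering).  Returns 1.0 for monomorphic input, which is
    handled by its own filter.
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype is required")
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n_hom_ref + n_het
    rare = min(n_alt, n_ref)
    if rare == 0:
        return 1.0

    # conditional log-probability of k heterozygotes given allele counts
    ks = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - ks) // 2
    hom_common = n - ks - hom_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(ks + 1)
        - gammaln(hom_common + 1)
        + ks * np.log(2.0)
        + gammaln(n_alt + 1)
        + gammaln(n_ref + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.nonzero(ks == n_het)[0][0]]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def filter_samples(
    genotypes: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop individuals whose genotype call rate is below threshold.

    Applied before any SNP filter; a call rate exactly at the threshold
    keeps the sample.
    """
    thresholds = thresholds or QcThresholds()
    rates = genotypes.sample_call_rates()
    keep = rates >= thresholds.sample_call_rate_min
    if not keep.any():
        raise ValueError("sample call-rate filter excluded every sample")
    excluded = [s for s, k in zip(genotypes.samples, keep) if not k]
    if excluded:
        genotypes = genotypes.subset_samples(keep)
    return genotypes, excluded


def _hwe_fails_by_group(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    thresholds: QcThresholds,
) -> tuple[np.ndarray, list[str]]:
    """Per-SNP flag: exact HWE test rejects in at least one ethnic group.

    Individuals with missing ethnicity are left out of the HWE test.
    """
    eth = covariates.set_index("id").reindex(genotypes.samples)["ethnicity"]
    fails = np.zeros(genotypes.n_snps, dtype=bool)
    detail = [""] * genotypes.n_snps
    for group in thresholds.hwe_groups:
        idx = np.flatnonzero((eth == group).to_numpy())
        if idx.size == 0:
            continue
        sub = genotypes.genotypes[:, idx]
        for i in range(genotypes.n_snps):
            g = sub[i]
            g = g[g != MISSING]
            if g.size == 0:
                continue
            p = hwe_exact_test(
                int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())
            )
            if p < thresholds.hwe_alpha:
                fails[i] = True
                detail[i] = f"{detail[i]},{group}" if detail[i] else group
    return fails, detail


def filter_snps(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    thresholds: QcThresholds | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the per-SNP filters and exclude the union of failures.

    The sample call-rate filter is applied first; SNP statistics are
    then computed on the retained samples only.
    """
    thresholds = thresholds or QcThresholds()
    rates = pd.Series(
        genotypes.sample_call_rates(), index=list(genotypes.samples)
    )
    genotypes, excluded_samples = filter_samples(genotypes, thresholds)

    g = genotypes.genotypes
    observed = g != MISSING
    n_obs = observed.sum(axis=1)
    if np.any(n_obs == 0):
        raise ValueError("a SNP has no called genotypes after sample QC")

    missing_fraction = genotypes.snp_missing_fractions()
    high_missing = missing_fraction > thresholds.snp_missing_max

    alt_counts = np.where(observed, g, 0).sum(axis=1)
    f_alt = alt_counts / (2.0 * n_obs)
    maf = np.minimum(f_alt, 1.0 - f_alt)
    low_maf = maf < thresholds.maf_min

    first = np.take_along_axis(
        g, np.argmax(observed, axis=1)[:, None], axis=1
    ).ravel()
    monomorphic = np.array(
        [
            np.all(g[i][observed[i]] == first[i])
            for i in range(genotypes.n_snps)
        ]
    )

    hwe_fail, hwe_detail = _hwe_fails_by_group(genotypes, covariates, thresholds)

    any_flag = monomorphic | high_missing | low_maf | hwe_fail
    per_snp = pd.DataFrame(
        {
            "snp_id": genotypes.snps["snp_id"],
            "gene": genotypes.snps["gene"],
            "maf": maf,
            "missing_fraction": missing_fraction,
            "monomorphic": monomorphic,
            "high_missing": high_missing,
            "low_maf": low_maf,
            "hwe_fail": hwe_fail,
            "hwe_fail_groups": hwe_detail,
            "excluded": any_flag,
        }
    )
    report = QCReport(
        per_snp=per_snp,
        category_counts={
            "monomorphic": int(monomorphic.sum()),
            "high_missing": int(high_missing.sum()),
            "low_maf": int(low_maf.sum()),
            "hwe_fail": int(hwe_fail.sum()),
        },
        excluded_union=int(any_flag.sum()),
        retained_snp_ids=list(genotypes.snps.loc[~any_flag, "snp_id"]),
        sample_call_rates=rates,
        excluded_samples=excluded_samples,
    )
    return genotypes.subset_snps(~any_flag), report


def encode_genotype(
    snp_id: str,
    genotypes: np.ndarray,
    ref: str = "A",
    alt: str = "G",
    recode_count_threshold: int = 15,
    recode_rule: str = "minor_homozygote",
    samples: list[str] | None = None,
) -> CodedGenotype:
    """Numeric coding for one QC-passing SNP.

    Additive coding (minor-allele copy count) by default; when the
    minor-homozygote count is at or below ``recode_count_threshold``
    the SNP is recoded to a dominant (carrier) contrast.  Setting
    ``recode_rule="any_category"`` applies the sparse-cell rule to all
    three genotype classes instead.
    """
    g = np.asarray(genotypes)
    obs = g[g != MISSING]
    if obs.size == 0:
        raise ValueError("cannot encode an all-missing SNP")
    if np.all(obs == obs[0]):
        raise ValueError("monomorphic SNP should have been removed by QC")

    f_alt = obs.sum() / (2.0 * obs.size)
    alt_is_minor = f_alt <= 0.5
    maf = float(min(f_alt, 1.0 - f_alt))
    values = np.where(g == MISSING, np.nan, g).astype(float)
    if not alt_is_minor:
        values = np.where(np.isnan(values), np.nan, 2.0 - values)
    minor, major = (alt, ref) if alt_is_minor else (ref, alt)

    counts = [(values == v).sum() for v in (0.0, 1.0, 2.0)]
    if recode_rule == "minor_homozygote":
        sparse = counts[2] <= recode_count_threshold
    elif recode_rule == "any_category":
        sparse = min(counts) <= recode_count_threshold
    else:
        raise ValueError(f"unknown recode_rule {recode_rule!r}")

    if sparse:
        values = np.where(np.isnan(values), np.nan, (values >= 1).astype(float))
        coding = "dominant"
    else:
        coding = "additive"
    return CodedGenotype(
        snp_id=snp_id,
        coding=coding,
        values=values,
        minor_allele=minor,
        major_allele=major,
        maf=maf,
        samples=list(samples) if samples is not None else None,
    )


def encode_all(
    genotypes: GenotypeMatrix,
    recode_count_threshold: int = 15,
    recode_rule: str = "minor_homozygote",
) -> list[CodedGenotype]:
    """Encode every SNP of a QC-passed matrix, preserving row order."""
    out = []
    for i, row in genotypes.snps.iterrows():
        out.append(
            encode_genotype(
                row["snp_id"],
                genotypes.genotypes[i],
                ref=row.get("ref", "A"),
                alt=row.get("alt", "G"),
                recode_count_threshold=recode_count_threshold,
                recode_rule=recode_rule,
                samples=genotypes.samples,
            )
        )
    return out
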