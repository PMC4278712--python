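"""Structure-preserving joint permutation inference.

The permutation unit is the individual: a permutation reassigns each
individual's full genotype vector (all SNPs at once) to another
individual's complete phenotype-and-covariate history (all phenotypes,
all cycles).  This breaks only the genotype-phenotype link while
preserving the LD between SNPs, the correlation between phenotypes,
the within-individual repeated-measures structure, and the
phenotype-covariate dependence.

Three corrections are computed from the B x T null matrix of raw
p-values: per-test permutation p-values (add-one convention),
Westfall-Young family-wise adjustment in its min-p form (the
per-permutation family minimum of p-values, the only statistic
commensurable across tests that mix codings and phenotype scales),
and Benjamini-Hochberg FDR applied to both raw and permutation
p-values across the full test family.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .lmm import ModelSpec, ScanResult, fit_lmm, run_scan
from .qc import CodedGenotype

__all__ = [
    "PermutationScheme",
    "PermutationNull",
    "AdjustedResults",
    "generate_permutations",
    "permutation_null",
    "permutation_pvalues",
    "westfall_young_minp",
    "bh_fdr",
    "assemble_adjusted",
    "scan_pvalue_function",
    "marginal_scan_pvalue_function",
]


@dataclass
class PermutationScheme:
    """Metadata for a permutation run."""

    n_permutations: int
    seed: int
    exhaustive: bool = False
    unit: str = "individual"
    action: str = (
        "reassign each individual's genotype vector to another "
        "individual's phenotype and covariate history"
    )


@dataclass
class PermutationNull:
    """Null distribution of the scan p-values.

    ``null`` is B x T (permutations x tests).  In exhaustive mode the
    enumeration includes the identity, so the observed configuration is
    one of the B rows and the plain count/B estimator is exact; in
    Monte-Carlo mode the add-one convention is used downstream.
    """

    null: np.ndarray
    observed: np.ndarray
    scheme: PermutationScheme

    def __post_init__(self) -> None:
        self.null = np.atleast_2d(np.asarray(self.null, dtype=float))
        self.observed = np.asarray(self.observed, dtype=float)
        if self.null.shape[1] != self.observed.shape[0]:
            raise ValueError("null matrix and observed vector disagree on T")

    @property
    def n_permutations(self) -> int:
        return self.null.shape[0]

    @property
    def n_tests(self) -> int:
        return self.null.shape[1]

    def min_p(self) -> np.ndarray:
        """Per-permutation family minimum p-value."""
        return self.null.min(axis=1)


@dataclass
class AdjustedResults:
    """Joined raw and adjusted p-values for the full test family."""

    table: pd.DataFrame
    alpha_star: float
    fwer_alpha: float
    scheme: PermutationScheme


def generate_permutations(
    n_individuals: int,
    n_permutations: int | None = None,
    seed: int = 0,
    exhaustive: bool = False,
) -> np.ndarray:
    """Permutations of individual indices, one per row.

    Monte-Carlo mode draws independent uniform permutations;
    exhaustive mode enumerates all n! bijections (identity included)
    and is restricted to small n.
    """
    if n_individuals < 2:
        raise ValueError("need at least two individuals to permute")
    if exhaustive:
        if n_individuals > 8:
            raise ValueError("exhaustive enumeration restricted to n <= 8")
        perms = np.array(
            list(itertools.permutations(range(n_individuals))), dtype=np.int64
        )
        return perms
    if n_permutations is None or n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    rng = np.random.default_rng(seed)
    return np.array(
        [rng.permutation(n_individuals) for _ in range(n_permutations)],
        dtype=np.int64,
    )


def permutation_null(
    fit_pvalues: Callable[[np.ndarray], np.ndarray],
    n_individuals: int,
    n_permutations: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermutationNull:
    """Build the B x T null matrix by refitting under each permutation.

    ``fit_pvalues`` maps a permutation (array ``perm`` where individual
    ``i`` receives the genotypes of individual ``perm[i]``) to the
    vector of raw p-values for all T tests, using the identical model
    specification as the observed analysis; the identity permutation
    therefore reproduces the observed p-values exactly.
    """
    perms = generate_permutations(
        n_individuals, n_permutations, seed=seed, exhaustive=exhaustive
    )
    observed = np.asarray(fit_pvalues(np.arange(n_individuals)), dtype=float)
    null = np.empty((len(perms), observed.shape[0]))
    for b, perm in enumerate(perms):
        null[b] = fit_pvalues(perm)
    scheme = PermutationScheme(
        n_permutations=len(perms), seed=seed, exhaustive=exhaustive
    )
    return PermutationNull(null=null, observed=observed, scheme=scheme)


def permutation_pvalues(null: PermutationNull) -> np.ndarray:
    """Per-test permutation p-values.

    Monte-Carlo: ``(1 + #{b: p_null[b,t] <= p_obs[t]}) / (B + 1)``
    (add-one convention; guarantees validity and p > 0).  Exhaustive:
    the plain proportion over the complete enumeration, which includes
    the identity and is therefore already positive.  Comparisons are on
    the p scale with an inclusive ``<=``, making smaller-is-more-extreme
    uniform across tests.
    """
    if np.isnan(null.null).any() or np.isnan(null.observed).any():
        bad = np.flatnonzero(
            np.isnan(null.null).any(axis=0) | np.isnan(null.observed)
        )
        raise ValueError(f"null p-values missing for tests {bad.tolist()}")
    count = (null.null <= null.observed[None, :]).sum(axis=0)
    B = null.n_permutations
    if null.scheme.exhaustive:
        return count / B
    return (1.0 + count) / (B + 1.0)


def westfall_young_minp(
    null: PermutationNull, fwer_alpha: float = 0.05
) -> tuple[np.ndarray, float]:
    """Westfall-Young family-wise adjustment, min-p form.

    For each test, the adjusted p-value is the permutation tail
    probability of the family minimum p falling at or below the
    observed p.  Also returns ``alpha_star``, the empirical
    ``fwer_alpha`` quantile of the family-minimum null distribution:
    the raw-p threshold controlling the family-wise error rate.
    Adjusted values dominate the per-test permutation p-values and are
    monotone in the observed p by construction.
    """
    minp = null.min_p()
    B = null.n_permutations
    if B * fwer_alpha < 1:
        warnings.warn(
            f"B={B} is too small to resolve the {fwer_alpha} quantile "
            "of the family-minimum null",
            stacklevel=2,
        )
    count = (minp[None, :] <= null.observed[:, None]).sum(axis=1)
    if null.scheme.exhaustive:
        adjusted = count / B
    else:
        adjusted = (1.0 + count) / (B + 1.0)
    alpha_star = float(np.quantile(minp, fwer_alpha))
    return adjusted, alpha_star


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Standard step-up with the running-minimum enforcement and a cap at
    1; ties receive equal adjusted values.  An empty input yields an
    empty output.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assemble_adjusted(
    scan: ScanResult,
    null: PermutationNull,
    fwer_alpha: float = 0.05,
) -> AdjustedResults:
    """Join every p-value column for the full scan family.

    FDR is applied across all T tests of the scan (not only nominal
    hits), separately to the raw mixed-model p-values and to the
    permutation p-values.
    """
    table = scan.table.copy()
    if len(table) != null.n_tests:
        raise ValueError(
            f"scan has {len(table)} tests but null matrix has {null.n_tests}"
        )
    p_perm = permutation_pvalues(null)
    p_maxt, alpha_star = westfall_young_minp(null, fwer_alpha)
    table["p_perm"] = p_perm
    table["fdr_raw"] = bh_fdr(table["p"].to_numpy())
    table["fdr_perm"] = bh_fdr(p_perm)
    table["p_maxt"] = p_maxt
    return AdjustedResults(
        table=table,
        alpha_star=alpha_star,
        fwer_alpha=fwer_alpha,
        scheme=null.scheme,
    )


# --------------------------------------------------------------------------
# fit functions for the permutation engine
# --------------------------------------------------------------------------

def scan_pvalue_function(
    genotypes,
    panel,
    covariates,
    codings: list[CodedGenotype] | None = None,
    model: ModelSpec | None = None,
    phenotypes: tuple[str, ...] | None = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Closure running the full mixed-model scan under a permutation.

    Codings (additive/dominant, minor-allele orientation) are assigned
    once from the observed data and held fixed; a permutation only
    relabels which individual carries which coded genotype vector, so
    covariates and phenotype histories stay together.
    """
    from .qc import encode_all

    if codings is None:
        codings = encode_all(genotypes)
    model = model or ModelSpec()

    def fit(perm: np.ndarray) -> np.ndarray:
        permuted = [
            replace(c, values=c.values[perm]) for c in codings
        ]
        scan = run_scan(
            genotypes, panel, covariates,
            codings=permuted, model=model, phenotypes=phenotypes,
        )
        return scan.pvalues()

    return fit


def marginal_scan_pvalue_function(
    genotype_matrix: np.ndarray, y: np.ndarray
) -> Callable[[np.ndarray], np.ndarray]:
    """Fast per-SNP regression p-values for calibration experiments.

    Degenerate case of the scan model — one observation per individual
    and no covariates — for which the mixed model collapses to simple
    linear regression of the phenotype on the genotype.  Returns the
    two-sided t-test p-value of the slope for every SNP, vectorised
    across the whole panel, so large permutation x replicate
    calibration grids stay cheap.
    """
    G = np.asarray(genotype_matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    if G.ndim != 2 or G.shape[1] != y.shape[0]:
        raise ValueError("genotype matrix must be (n_snps, n_individuals)")
    n = y.shape[0]
    Gc = G - G.mean(axis=1, keepdims=True)
    sg = np.sqrt((Gc**2).sum(axis=1))

    def fit(perm: np.ndarray) -> np.ndarray:
        Gp = Gc[:, perm]
        yc = y - y.mean()
        sy = math.sqrt(float((yc**2).sum()))
        r = (Gp @ yc) / (sg * sy)
        r = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        return 2.0 * t_dist.sf(np.abs(t), df=n - 2)

    return fit
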