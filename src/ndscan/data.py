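"""Shared in-memory containers for the association pipeline.

The pipeline operates on two primary objects: a :class:`GenotypeMatrix`
(SNP x individual integer genotypes with a missingness sentinel and
per-SNP metadata) and a :class:`PhenotypePanel` (long-format repeated
measures of six phenotypes, with one observation row per individual per
data-collection cycle).  Covariates (sex, ethnicity) are carried as a
plain one-row-per-individual :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the integer matrix.
MISSING = -1

#: Canonical phenotype order used throughout the pipeline.  The first
#: phenotype is a count (cigarettes smoked in the past three months) and
#: is analysed on the natural-log scale; the other five are
#: questionnaire-derived nicotine-dependence scores treated as continuous.
PHENOTYPES = (
    "cigarettes",
    "nd_craving",
    "icd10",
    "mftq",
    "self_medication",
    "withdrawal",
)

#: Phenotypes stored as non-negative counts and log-transformed before
#: model fitting.
COUNT_PHENOTYPES = ("cigarettes",)

#: Ethnicity categories; the first is the model reference category.
ETHNICITIES = ("french_canadian", "european", "other")


@dataclass
class GenotypeMatrix:
    """SNP x individual genotype matrix with per-SNP metadata.

    Parameters
    ----------
    genotypes
        Integer array of shape ``(n_snps, n_samples)`` holding minor- or
        alt-allele copy counts 0/1/2, with :data:`MISSING` (-1) for a
        failed call.  Stored as a small signed integer dtype.
    snps
        Metadata table, one row per SNP and positionally aligned with the
        rows of ``genotypes``.  Required columns: ``snp_id``, ``gene``,
        ``chrom``, ``pos``, ``ref``, ``alt``.  The synthetic generator
        adds an ``injected`` column naming any deliberately planted
        defect category.
    samples
        Individual identifiers, aligned with the columns.
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D array")
        if len(self.snps) != self.genotypes.shape[0]:
            raise ValueError("snps metadata does not match genotype rows")
        if len(self.samples) != self.genotypes.shape[1]:
            raise ValueError("samples do not match genotype columns")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp_id"])

    def vector(self, snp_id: str) -> np.ndarray:
        """Return the genotype row for one SNP (copy)."""
        idx = self.snps.index[self.snps["snp_id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"unknown SNP {snp_id!r}")
        return self.genotypes[idx[0]].copy()

    def sample_call_rates(self) -> np.ndarray:
        """Fraction of non-missing calls per individual."""
        return (self.genotypes != MISSING).mean(axis=0)

    def snp_missing_fractions(self) -> np.ndarray:
        """Fraction of missing calls per SNP."""
        return (self.genotypes == MISSING).mean(axis=1)

    def subset_snps(self, mask: Sequence[bool] | np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            genotypes=self.genotypes[mask].copy(),
            snps=self.snps.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
        )

    def subset_samples(self, keep: Sequence[bool] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=bool)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, keep].copy(),
            snps=self.snps.copy(),
            samples=[s for s, k in zip(self.samples, keep) if k],
        )


@dataclass
class PhenotypePanel:
    """Long-format repeated measures of the study phenotypes.

    ``observations`` has one row per (individual, cycle) with columns
    ``id``, ``cycle``, ``age`` and one column per phenotype.  Phenotypes
    listed in ``count_phenotypes`` are stored on the raw count scale and
    log-transformed by the model layer.
    """

    observations: pd.DataFrame
    phenotypes: tuple[str, ...] = PHENOTYPES
    count_phenotypes: tuple[str, ...] = COUNT_PHENOTYPES

    def __post_init__(self) -> None:
        required = {"id", "cycle", "age", *self.phenotypes}
        missing = required - set(self.observations.columns)
        if missing:
            raise ValueError(f"panel is missing columns {sorted(missing)}")

    @property
    def individuals(self) -> np.ndarray:
        return self.observations["id"].unique()

    def n_observations(self) -> int:
        return len(self.observations)
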