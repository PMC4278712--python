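"""QC-layer checks: MAF, the exact Hardy-Weinberg test against a full
enumeration oracle, the sample/SNP filters and the genotype codings."""

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ndscan as nd
from ndscan.data import MISSING, GenotypeMatrix
from ndscan.qc import (
    QcThresholds,
    compute_maf,
    encode_genotype,
    filter_samples,
    filter_snps,
    hwe_exact_test,
)


def hwe_enumeration_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Brute-force exact HWE p-value with rational arithmetic.

    Enumerates every heterozygote count compatible with the conditional
    allele counts and sums the exact probabilities that do not exceed
    the observed configuration's probability.
    """
    n = n_hom_ref + n_het + n_hom_alt
    rare = min(2 * n_hom_alt + n_het, 2 * n_hom_ref + n_het)
    if rare == 0:
        return 1.0
    weights = {}
    for k in range(rare % 2, rare + 1, 2):
        d_rare = (rare - k) // 2
        d_common = n - k - d_rare
        weights[k] = Fraction(
            factorial(n), factorial(d_rare) * factorial(k) * factorial(d_common)
        ) * 2**k
    total = sum(weights.values())
    w_obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= w_obs) / total)


class TestComputeMaf:
    @pytest.mark.parametrize(
        "vector, expected",
        [
            ([1, 1, 1, 1], 0.5),
            ([0, 0, 1, 2], 0.375),
            ([0, 0, 0, 0], 0.0),
            ([2, 2, 2, 2], 0.0),
            ([0, MISSING, 0, 1, 2, MISSING], 0.375),
        ],
    )
    def test_examples(self, vector, expected):
        assert compute_maf(np.array(vector)) == pytest.approx(expected)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            compute_maf(np.array([MISSING, MISSING]))

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1, max_size=60)
        .filter(lambda v: any(x != MISSING for x in v))
    )
    def test_allele_swap_invariance(self, vector):
        g = np.array(vector)
        flipped = np.where(g == MISSING, MISSING, 2 - g)
        assert compute_maf(g) == pytest.approx(compute_maf(flipped))


class TestHweExactTest:
    def test_modal_configuration_has_p_one(self):
        # (25, 50, 25): observed heterozygote count is the conditional mode
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_extreme_heterozygote_deficit(self):
        assert hwe_exact_test(50, 0, 50) < 1e-10

    def test_monomorphic_convention(self):
        assert hwe_exact_test(0, 0, 10) == 1.0
        assert hwe_exact_test(10, 0, 0) == 1.0

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        cases = [(25, 50, 25), (50, 0, 50), (1, 1, 1), (0, 1, 0), (3, 17, 40)]
        while len(cases) < 60:
            total = int(rng.integers(1, 101))
            a = int(rng.integers(0, total + 1))
            b = int(rng.integers(0, total - a + 1))
            cases.append((a, b, total - a - b))
        for counts in cases:
            expected = hwe_enumeration_oracle(*counts)
            assert hwe_exact_test(*counts) == pytest.approx(
                expected, abs=1e-12
            ), counts


def _matrix(geno, samples=None):
    geno = np.asarray(geno, dtype=np.int8)
    m, n = geno.shape
    samples = samples or [f"s{i}" for i in range(n)]
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(m)],
            "gene": "G1",
            "chrom": "1",
            "pos": np.arange(m) + 1,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(genotypes=geno, snps=snps, samples=samples)


class TestFilterSamples:
    def test_complete_matrix_keeps_everyone(self):
        gm = _matrix(np.zeros((4, 6)))
        _, excluded = filter_samples(gm)
        assert excluded == []

    def test_low_call_rate_sample_excluded(self):
        geno = np.ones((10, 3), dtype=np.int8)
        geno[1:, 0] = MISSING  # sample 0: 10% call rate
        gm = _matrix(geno)
        filtered, excluded = filter_samples(gm)
        assert excluded == ["s0"]
        assert filtered.n_samples == 2

    def test_boundary_call_rate_is_retained(self):
        # exactly 0.95: 19 of 20 SNPs called
        geno = np.ones((20, 2), dtype=np.int8)
        geno[0, 0] = MISSING
        _, excluded = filter_samples(_matrix(geno))
        assert excluded == []


class TestFilterSnps:
    def test_engineered_panel_realizes_published_counts(self, qc_filtered):
        retained, report, _ = qc_filtered
        assert report.excluded_union == 73
        assert retained.n_snps == 321
        assert report.category_counts["monomorphic"] == 3
        assert report.category_counts["high_missing"] == 3
        assert report.category_counts["low_maf"] == 51  # includes monomorphic
        assert report.category_counts["hwe_fail"] == 19

    def test_clean_matrix_excludes_nothing(self):
        # genotype counts exactly at Hardy-Weinberg proportions for p=0.3
        row = np.array([0] * 98 + [1] * 84 + [2] * 18, dtype=np.int8)
        geno = np.tile(row, (10, 1))
        cov = pd.DataFrame(
            {"id": [f"s{i}" for i in range(200)], "sex": 0,
             "ethnicity": "french_canadian"}
        )
        retained, report = filter_snps(_matrix(geno), cov)
        assert report.excluded_union == 0
        assert retained.n_snps == 10

    def test_maf_exactly_at_threshold_is_retained(self):
        # 1 het among 10 individuals: MAF exactly 0.05
        geno = np.zeros((1, 10), dtype=np.int8)
        geno[0, 0] = 1
        cov = pd.DataFrame(
            {"id": [f"s{i}" for i in range(10)], "sex": 0,
             "ethnicity": "french_canadian"}
        )
        _, report = filter_snps(_matrix(geno), cov)
        assert report.per_snp.loc[0, "maf"] == pytest.approx(0.05)
        assert not report.per_snp.loc[0, "low_maf"]

    def test_idempotence(self, qc_filtered):
        retained, _, covariates = qc_filtered
        again, report = filter_snps(retained, covariates)
        assert report.excluded_union == 0
        assert again.n_snps == retained.n_snps

    def test_flags_invariant_under_row_permutation(self, qc_panel):
        genotypes, covariates = qc_panel
        _, report = filter_snps(genotypes, covariates)
        rng = np.random.default_rng(3)
        order = rng.permutation(genotypes.n_snps)
        shuffled = GenotypeMatrix(
            genotypes=genotypes.genotypes[order],
            snps=genotypes.snps.iloc[order].reset_index(drop=True),
            samples=list(genotypes.samples),
        )
        _, report2 = filter_snps(shuffled, covariates)
        a = report.per_snp.set_index("snp_id").sort_index()
        b = report2.per_snp.set_index("snp_id").sort_index()
        for col in ("monomorphic", "high_missing", "low_maf", "hwe_fail"):
            assert a[col].equals(b[col])


class TestEncodeGenotype:
    @staticmethod
    def _vector(n_hom_major, n_het, n_hom_minor):
        return np.array(
            [0] * n_hom_major + [1] * n_het + [2] * n_hom_minor, dtype=np.int8
        )

    def test_common_snp_stays_additive(self):
        coded = encode_genotype("rs1", self._vector(300, 200, 44))
        assert coded.coding == "additive"
        assert set(np.unique(coded.values)) <= {0.0, 1.0, 2.0}

    def test_sparse_minor_homozygotes_recode_to_dominant(self):
        coded = encode_genotype("rs1", self._vector(400, 130, 14))
        assert coded.coding == "dominant"
        # carriers of the minor allele are coded 1
        assert coded.values.sum() == 130 + 14

    def test_boundary_count_fifteen_recodes(self):
        coded = encode_genotype("rs1", self._vector(400, 130, 15))
        assert coded.coding == "dominant"

    def test_minor_allele_orientation(self):
        # alt allele is the major one here; coding must count ref copies
        g = np.array([2] * 90 + [1] * 40 + [0] * 30, dtype=np.int8)
        coded = encode_genotype("rs1", g, ref="A", alt="G")
        assert coded.minor_allele == "A"
        assert coded.maf == pytest.approx((40 + 60) / 320)
        assert coded.values[0] == 0.0  # alt-hom carries 0 minor alleles

    def test_monomorphic_raises(self):
        with pytest.raises(ValueError):
            encode_genotype("rs1", np.zeros(50, dtype=np.int8))

    def test_thresholds_validate(self):
        with pytest.raises(ValueError):
            QcThresholds(maf_min=1.5)
        with pytest.raises(ValueError):
            QcThresholds(hwe_alpha=0.0)
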