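"""Permutation engine and multiple-testing corrections: bijection
structure, add-one / exhaustive conventions, the exhaustive refit
oracle, Westfall-Young min-p and BH-FDR step-up behaviour."""

from dataclasses import replace

import numpy as np
import pytest

import ndscan as nd
from ndscan.lmm import ModelSpec, fit_lmm
from ndscan.permutation import (
    PermutationNull,
    PermutationScheme,
    assemble_adjusted,
    bh_fdr,
    generate_permutations,
    marginal_scan_pvalue_function,
    permutation_null,
    permutation_pvalues,
    scan_pvalue_function,
    westfall_young_minp,
)


def _null(null_matrix, observed, exhaustive=False, seed=0):
    scheme = PermutationScheme(
        n_permutations=len(null_matrix), seed=seed, exhaustive=exhaustive
    )
    return PermutationNull(null=np.asarray(null_matrix, dtype=float),
                           observed=np.asarray(observed, dtype=float),
                           scheme=scheme)


class TestGeneratePermutations:
    def test_rows_are_bijections(self):
        perms = generate_permutations(20, 50, seed=1)
        assert perms.shape == (50, 20)
        for row in perms:
            assert np.array_equal(np.sort(row), np.arange(20))

    def test_exhaustive_enumerates_all_distinct(self):
        perms = generate_permutations(4, exhaustive=True)
        assert perms.shape == (24, 4)
        assert len({tuple(p) for p in perms}) == 24

    def test_seed_determinism(self):
        a = generate_permutations(10, 30, seed=5)
        b = generate_permutations(10, 30, seed=5)
        c = generate_permutations(10, 30, seed=6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_exhaustive_guard(self):
        with pytest.raises(ValueError):
            generate_permutations(12, exhaustive=True)


class TestPermutationPvalues:
    def test_observed_smaller_than_all_null(self):
        null = _null(np.linspace(0.1, 0.9, 99)[:, None], [0.01])
        assert permutation_pvalues(null)[0] == pytest.approx(0.01)

    def test_observed_larger_than_all_null(self):
        null = _null(np.linspace(0.001, 0.5, 99)[:, None], [0.9])
        assert permutation_pvalues(null)[0] == pytest.approx(1.0)

    def test_missing_null_entries_raise(self):
        matrix = np.full((10, 2), 0.5)
        matrix[3, 1] = np.nan
        with pytest.raises(ValueError, match="tests \\[1\\]"):
            permutation_pvalues(_null(matrix, [0.5, 0.5]))

    def test_bounds(self):
        rng = np.random.default_rng(0)
        null = _null(rng.uniform(size=(200, 5)), rng.uniform(size=5))
        p = permutation_pvalues(null)
        assert np.all(p >= 1.0 / 201.0)
        assert np.all(p <= 1.0)


class TestIdentityAndInvariance:
    def test_identity_permutation_reproduces_observed_fit(self, small_scan):
        retained, codings, scan, panel, covariates = small_scan
        sub = retained.subset_snps(np.arange(retained.n_snps) < 2)
        sub_codings = codings[:2]
        fit = scan_pvalue_function(sub, panel, covariates,
                                   codings=sub_codings)
        observed = fit(np.arange(sub.n_samples))
        expected = scan.table.set_index(["snp_id", "phenotype"])
        for i, coded in enumerate(sub_codings):
            for j, pheno in enumerate(nd.PHENOTYPES):
                assert observed[i * 6 + j] == expected.loc[
                    (coded.snp_id, pheno), "p"
                ]

    def test_permutation_preserves_marginals(self, small_scan):
        retained, codings, _, _, _ = small_scan
        rng = np.random.default_rng(4)
        perm = rng.permutation(retained.n_samples)
        coded = codings[0]
        a, b = coded.values, coded.values[perm]
        assert sorted(a[~np.isnan(a)]) == sorted(b[~np.isnan(b)])


class TestExhaustiveOracle:
    def test_exhaustive_permutation_p_equals_brute_force_refits(self):
        """n=5 individuals, all 120 bijections: the engine's permutation
        p must equal an independent loop that refits each relabelling."""
        import pandas as pd

        design = nd.CohortDesign(n_individuals=5, n_cycles=8,
                                 dropout_rate=0.0)
        spec = nd.SnpSpec(n_snps=1, maf_range=(0.4, 0.4), missing_rate=0.0)
        genotypes = nd.simulate_genotypes(design, spec, seed=21)
        # constant covariates: with five individuals the genotype must be
        # the only between-person regressor or some relabellings are
        # exactly collinear and unidentifiable
        covariates = pd.DataFrame(
            {"id": genotypes.samples, "sex": 0,
             "ethnicity": "french_canadian"}
        )
        panel = nd.simulate_phenotypes(
            genotypes, covariates, design, nd.EffectSpec(), seed=22
        )
        # ensure the lone SNP is polymorphic in this tiny draw
        assert np.ptp(genotypes.genotypes[0]) > 0
        codings = nd.encode_all(genotypes)
        model = ModelSpec(min_individuals=2)
        fit = scan_pvalue_function(
            genotypes, panel, covariates, codings=codings, model=model,
            phenotypes=("withdrawal",),
        )
        null = permutation_null(fit, 5, exhaustive=True)
        engine_p = permutation_pvalues(null)[0]

        # independent brute force: refit every relabelling directly
        count = 0
        p_obs = fit_lmm(panel, covariates, codings[0], "withdrawal",
                        model=model).p
        import itertools

        for perm in itertools.permutations(range(5)):
            coded = replace(codings[0],
                            values=codings[0].values[np.array(perm)])
            p_b = fit_lmm(panel, covariates, coded, "withdrawal",
                          model=model).p
            count += p_b <= p_obs
        assert engine_p == count / 120.0


class TestWestfallYoung:
    def test_single_test_family_equals_permutation_p(self):
        rng = np.random.default_rng(1)
        null = _null(rng.uniform(size=(500, 1)), [0.02])
        adjusted, _ = westfall_young_minp(null)
        assert adjusted[0] == pytest.approx(permutation_pvalues(null)[0])

    def test_adjustment_orderings(self):
        rng = np.random.default_rng(2)
        null = _null(rng.uniform(size=(300, 8)), rng.uniform(0, 0.2, size=8))
        p_perm = permutation_pvalues(null)
        p_maxt, alpha_star = westfall_young_minp(null)
        assert np.all(p_maxt >= p_perm)
        assert np.all(p_perm >= 1.0 / 301.0)
        # monotone in the observed p
        order = np.argsort(null.observed)
        assert np.all(np.diff(p_maxt[order]) >= 0)
        assert 0.0 < alpha_star < 0.2

    def test_small_b_warns(self):
        null = _null(np.full((10, 3), 0.5), [0.5, 0.5, 0.5])
        with pytest.warns(UserWarning, match="too small"):
            westfall_young_minp(null, fwer_alpha=0.05)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_hand_computed_step_up(self):
        adjusted = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_equal_values_map_to_themselves(self):
        adjusted = bh_fdr([0.2] * 7)
        assert np.allclose(adjusted, 0.2)

    def test_ties_get_equal_adjusted_values(self):
        adjusted = bh_fdr([0.011, 0.011, 0.5, 0.9])
        assert adjusted[0] == adjusted[1]

    def test_order_restored(self):
        p = [0.9, 0.001, 0.5, 0.04]
        adjusted = bh_fdr(p)
        assert np.argmin(adjusted) == 1

    def test_empty_and_invalid(self):
        assert bh_fdr([]).size == 0
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestAssembleAdjusted:
    @pytest.fixture(scope="class")
    def adjusted(self, small_scan):
        from ndscan.lmm import run_scan

        retained, codings, _, panel, covariates = small_scan
        # small family (planted SNP plus two nulls), small B: enough to
        # exercise every joining rule without a long refit loop
        keep = np.isin(retained.snp_ids,
                       ["snp_0000", "snp_0003", "snp_0006"])
        sub = retained.subset_snps(keep)
        sub_codings = [c for c in codings if c.snp_id in set(sub.snp_ids)]
        scan = run_scan(sub, panel, covariates, codings=sub_codings)
        fit = scan_pvalue_function(sub, panel, covariates,
                                   codings=sub_codings)
        null = permutation_null(fit, sub.n_samples,
                                n_permutations=19, seed=8)
        return scan, null, assemble_adjusted(scan, null)

    def test_all_adjusted_dominate_unadjusted(self, adjusted):
        scan, null, res = adjusted
        t = res.table
        assert np.all(t["fdr_raw"] >= t["p"] - 1e-12)
        assert np.all(t["fdr_perm"] >= t["p_perm"] - 1e-12)
        assert np.all(t["p_maxt"] >= t["p_perm"] - 1e-12)

    def test_planted_effect_ranks_first(self, adjusted):
        scan, null, res = adjusted
        t = res.table
        best = t.loc[t["p"].idxmin()]
        assert (best["snp_id"], best["phenotype"]) == ("snp_0006", "mftq")

    def test_dimension_mismatch_raises(self, adjusted, small_scan):
        scan, null, _ = adjusted
        truncated = _null(null.null[:, :5], null.observed[:5])
        with pytest.raises(ValueError, match="tests"):
            assemble_adjusted(scan, truncated)

    def test_seed_reproducibility(self, small_scan):
        retained, codings, scan, panel, covariates = small_scan
        sub = retained.subset_snps(np.arange(retained.n_snps) < 1)
        fit = scan_pvalue_function(sub, panel, covariates,
                                   codings=codings[:1],
                                   phenotypes=("icd10",))
        a = permutation_null(fit, sub.n_samples, 7, seed=13)
        b = permutation_null(fit, sub.n_samples, 7, seed=13)
        assert np.array_equal(a.null, b.null)


class TestMarginalFastPath:
    def test_matches_naive_regression(self):
        from scipy import stats

        rng = np.random.default_rng(9)
        G = rng.binomial(2, 0.3, size=(4, 80)).astype(float)
        y = rng.normal(size=80)
        fit = marginal_scan_pvalue_function(G, y)
        p = fit(np.arange(80))
        for i in range(4):
            res = stats.linregress(G[i], y)
            assert p[i] == pytest.approx(res.pvalue, rel=1e-9)
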