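import warnings

import numpy as np
import pytest

import ndscan as nd

# optimizer restarts occasionally emit harmless runtime warnings from
# infeasible variance parameters; keep test output clean
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def qc_panel():
    """Engineered 394-SNP QC panel at n=150 with its covariates."""
    return nd.reference_qc_panel(n_individuals=150, seed=2025)


@pytest.fixture(scope="session")
def qc_filtered(qc_panel):
    genotypes, covariates = qc_panel
    retained, report = nd.filter_snps(genotypes, covariates)
    return retained, report, covariates


@pytest.fixture(scope="session")
def small_cohort():
    """Small simulated cohort with LD blocks and one planted effect."""
    design = nd.CohortDesign(n_individuals=200, n_cycles=5, dropout_rate=0.02)
    spec = nd.SnpSpec(n_snps=8, ld_blocks=[(2, 1.0), (2, 0.8)])
    effects = nd.EffectSpec(causal_effects={"snp_0006": {"mftq": 0.6}})
    genotypes, panel, covariates = nd.simulate_cohort(design, spec, effects, seed=42)
    return genotypes, panel, covariates


@pytest.fixture(scope="session")
def small_scan(small_cohort):
    genotypes, panel, covariates = small_cohort
    retained, _ = nd.filter_snps(genotypes, covariates)
    codings = nd.encode_all(retained)
    scan = nd.run_scan(retained, panel, covariates, codings=codings)
    return retained, codings, scan, panel, covariates
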