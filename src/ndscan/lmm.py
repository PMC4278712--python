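"""Linear mixed model scan over SNP x phenotype pairs.

Model, for individual *i* at observation *j*:

    y_ij = b0 + b_g * g_i + b_sex * sex_i + ethnicity contrasts
           + b1 * agec_ij + b2 * agec_ij^2 + u0_i + u1_i * agec_ij + e_ij

with ``(u0_i, u1_i)`` a per-individual random intercept and random
linear age slope with unstructured 2x2 covariance, independent
homoscedastic residuals, and age centered at the sample mean (the
centering affects only the intercept, not the SNP coefficient).  The
count phenotype enters as ln(count + 1).

Estimation is REML (ML available) via a profiled likelihood: the 2x2
random-effect covariance is parameterised by its scaled Cholesky
factor (log-diagonal), fixed effects and the residual variance are
profiled out in closed form, and all per-cluster terms reduce to 2x2
algebra through the Woodbury identity on per-cluster sufficient
statistics.  This makes a fit cost milliseconds, which is what renders
the joint permutation scan tractable.  Inference on the SNP
coefficient is a Wald z test; the permutation layer, not the normal
approximation, carries the final inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .data import ETHNICITIES, PHENOTYPES, PhenotypePanel
from .qc import CodedGenotype

__all__ = [
    "ModelSpec",
    "FitResult",
    "ScanResult",
    "transform_count_phenotype",
    "fit_lmm",
    "run_scan",
    "nominal_hits",
    "hit_grid",
]


@dataclass
class ModelSpec:
    """Options for the mixed-model fit.

    ``random_effects`` selects the random structure: the full
    intercept+slope model, a random-intercept-only model, or ``"none"``
    which reduces the fit to ordinary least squares (the degenerate
    limit of the mixed model; used for validation).
    """

    random_effects: str = "intercept_slope"  # | "intercept" | "none"
    reml: bool = True
    min_individuals: int = 30
    log_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.random_effects not in ("intercept_slope", "intercept", "none"):
            raise ValueError(f"unknown random_effects {self.random_effects!r}")


@dataclass
class FitResult:
    """Result of one SNP x phenotype fit."""

    snp_id: str
    phenotype: str
    coding: str
    beta: float
    se: float
    p: float
    n_individuals: int
    n_observations: int
    status: str  # "ok" | "ok_intercept_only" | "failed"
    var_intercept: float = np.nan
    var_slope: float = np.nan
    cov_intercept_slope: float = np.nan
    var_residual: float = np.nan
    neg2_criterion: float = np.nan
    #: Variance-parameter vector at the optimum (internal; used for
    #: warm-starting neighbouring fits).
    theta: np.ndarray | None = None

    @property
    def converged(self) -> bool:
        return self.status.startswith("ok")


@dataclass
class ScanResult:
    """Scan table: one row per SNP x phenotype pair, in deterministic
    order (SNP genomic order outer, fixed phenotype order inner)."""

    table: pd.DataFrame
    phenotypes: tuple[str, ...]
    model: ModelSpec

    @property
    def n_tests(self) -> int:
        return len(self.table)

    def pvalues(self) -> np.ndarray:
        return self.table["p"].to_numpy()


def transform_count_phenotype(
    counts: np.ndarray, offset: float = 1.0
) -> np.ndarray:
    """Natural-log transform for the count phenotype: ln(count + offset).

    The unit offset maps a zero-cigarette observation to 0 on the
    analysis scale.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts[~np.isnan(counts)] < 0):
        raise ValueError("counts must be non-negative")
    return np.log(counts + offset)


# --------------------------------------------------------------------------
# profiled REML machinery
# --------------------------------------------------------------------------

class _MixedData:
    """Per-cluster sufficient statistics for the profiled likelihood.

    Requires rows sorted by cluster.  ``Z`` holds the random-effect
    design ([1, agec]); all likelihood evaluations reduce to batched
    q x q (q <= 2) operations over clusters.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, Z: np.ndarray,
                 clusters: np.ndarray) -> None:
        order = np.argsort(clusters, kind="stable")
        y, X, Z, clusters = y[order], X[order], Z[order], clusters[order]
        _, starts = np.unique(clusters, return_index=True)
        self.N, self.p = X.shape
        self.q = Z.shape[1]
        self.n_clusters = len(starts)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # reduceat-based segment sums of the outer products
        zz = (Z[:, :, None] * Z[:, None, :]).reshape(self.N, -1)
        zx = (Z[:, :, None] * X[:, None, :]).reshape(self.N, -1)
        zy = Z * y[:, None]
        self.Szz = np.add.reduceat(zz, starts, axis=0).reshape(-1, self.q, self.q)
        self.Szx = np.add.reduceat(zx, starts, axis=0).reshape(-1, self.q, self.p)
        self.Szy = np.add.reduceat(zy, starts, axis=0)

    # -- likelihood -------------------------------------------------------

    def _cholesky(self, theta: np.ndarray) -> np.ndarray:
        """Scaled Cholesky factor L of the random-effect covariance
        (relative to the residual variance) from the unconstrained
        parameter vector."""
        if self.q == 1:
            return np.array([[np.exp(theta[0])]])
        return np.array(
            [[np.exp(theta[0]), 0.0], [theta[2], np.exp(theta[1])]]
        )

    def _solve(self, theta: np.ndarray):
        """Profiled GLS pieces at the given variance parameters.

        Returns (XVX, XVy, yVy, sum log det M) with V_i implicit via
        Woodbury, or None when numerically infeasible.
        """
        L = self._cholesky(theta)
        M = np.einsum("ab,nbc,cd->nad", L.T, self.Szz, L)
        M[:, np.arange(self.q), np.arange(self.q)] += 1.0
        if self.q == 1:
            det = M[:, 0, 0]
            if np.any(det <= 0):
                return None
            Minv = (1.0 / det)[:, None, None]
        else:
            det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
            if np.any(det <= 0):
                return None
            Minv = np.empty_like(M)
            Minv[:, 0, 0] = M[:, 1, 1]
            Minv[:, 1, 1] = M[:, 0, 0]
            Minv[:, 0, 1] = -M[:, 0, 1]
            Minv[:, 1, 0] = -M[:, 1, 0]
            Minv /= det[:, None, None]
        U = np.einsum("ab,nbp->nap", L.T, self.Szx)
        v = np.einsum("ab,nb->na", L.T, self.Szy)
        XVX = self.XtX - np.einsum("nap,nab,nbq->pq", U, Minv, U)
        XVy = self.Xty - np.einsum("nap,nab,nb->p", U, Minv, v)
        yVy = self.yty - np.einsum("na,nab,nb->", v, Minv, v)
        return XVX, XVy, yVy, float(np.log(det).sum())

    def neg2(self, theta: np.ndarray, reml: bool = True) -> float:
        """Profiled -2 log-likelihood (restricted when ``reml``), up to
        an additive constant."""
        pieces = self._solve(theta)
        if pieces is None:
            return np.inf
        XVX, XVy, yVy, logdet = pieces
        if not np.all(np.isfinite(XVX)):
            return np.inf
        try:
            c = np.linalg.cholesky(XVX)
            beta = np.linalg.solve(XVX, XVy)
        except np.linalg.LinAlgError:
            return np.inf
        rss = yVy - XVy @ beta
        if not np.isfinite(rss) or rss <= 0:
            return np.inf
        if reml:
            dof = self.N - self.p
            return (
                dof * np.log(rss / dof)
                + logdet
                + 2.0 * np.log(np.diag(c)).sum()
            )
        return self.N * np.log(rss / self.N) + logdet

    def estimates(self, theta: np.ndarray, reml: bool = True):
        """(beta, cov_beta, s2, G) at the given variance parameters."""
        pieces = self._solve(theta)
        if pieces is None:
            raise np.linalg.LinAlgError("infeasible variance parameters")
        XVX, XVy, yVy, _ = pieces
        beta = np.linalg.solve(XVX, XVy)
        rss = yVy - XVy @ beta
        dof = self.N - self.p if reml else self.N
        s2 = rss / dof
        cov_beta = np.linalg.inv(XVX) * s2
        L = self._cholesky(theta)
        G = s2 * (L @ L.T)
        return beta, cov_beta, float(s2), G

    def ols(self):
        """Degenerate fit with no random effects (V = I)."""
        beta = np.linalg.solve(self.XtX, self.Xty)
        rss = self.yty - self.Xty @ beta
        s2 = rss / (self.N - self.p)
        cov_beta = np.linalg.inv(self.XtX) * s2
        return beta, cov_beta, float(s2)


_NM_OPTIONS = dict(xatol=1e-6, fatol=1e-9, maxiter=4000)


def _optimize(data: _MixedData, reml: bool, start: np.ndarray | None):
    n_params = 3 if data.q == 2 else 1
    starts = []
    if start is not None and len(np.atleast_1d(start)) == n_params:
        starts.append(np.asarray(start, dtype=float))
    if data.q == 2:
        starts += [np.array([-0.5, -1.5, 0.0]), np.array([-2.0, -2.0, 0.0])]
    else:
        starts += [np.array([-0.5]), np.array([-2.0])]
    best = None
    for x0 in starts:
        res = minimize(
            data.neg2, x0, args=(reml,), method="Nelder-Mead",
            options=_NM_OPTIONS,
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-10):
            best = res
        if best is not None and best.success:
            break
    return best


def _fit_arrays(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    clusters: np.ndarray,
    model: ModelSpec,
    start: np.ndarray | None = None,
):
    """Fit the mixed model on assembled arrays.

    Returns a dict with estimates plus a status from the fallback
    ladder: full model, restart, then random-intercept-only; an OLS
    refit replaces a fit whose random-effect variance collapsed to a
    numerically singular covariance.
    """
    out = {
        "beta": None, "cov_beta": None, "s2": np.nan,
        "G": None, "status": "failed", "criterion": np.nan, "theta": None,
    }
    if model.random_effects == "none":
        data = _MixedData(y, X, Z[:, :1], clusters)
        beta, cov_beta, s2 = data.ols()
        out.update(beta=beta, cov_beta=cov_beta, s2=s2,
                   G=np.zeros((2, 2)), status="ok",
                   criterion=data.neg2(np.array([-30.0]), model.reml))
        return out

    q_primary = 2 if model.random_effects == "intercept_slope" else 1
    data = _MixedData(y, X, Z[:, :q_primary], clusters)
    res = _optimize(data, model.reml, start)
    status = "ok"
    if res is None or not res.success:
        if q_primary == 2:  # drop the random slope and retry
            data = _MixedData(y, X, Z[:, :1], clusters)
            res = _optimize(data, model.reml, None)
            status = "ok_intercept_only"
        if res is None or not res.success:
            return out
    try:
        beta, cov_beta, s2, G = data.estimates(res.x, model.reml)
    except np.linalg.LinAlgError:
        return out
    se = np.sqrt(np.diag(cov_beta))
    if not np.all(np.isfinite(se)):
        return out
    if data.q == 1:
        G = np.array([[G[0, 0], np.nan], [np.nan, np.nan]])
    out.update(beta=beta, cov_beta=cov_beta, s2=s2, G=G,
               status=status, criterion=float(res.fun), theta=res.x)
    return out


# --------------------------------------------------------------------------
# data assembly and public fitting interface
# --------------------------------------------------------------------------

def _analysis_frame(
    panel: PhenotypePanel,
    covariates: pd.DataFrame,
    phenotype: str,
    model: ModelSpec,
) -> pd.DataFrame:
    """Observation table for one phenotype with covariates attached.

    Observation-level deletion for missing phenotype/age;
    individual-level deletion for missing sex/ethnicity.
    """
    if phenotype not in panel.phenotypes:
        raise KeyError(f"unknown phenotype {phenotype!r}")
    obs = panel.observations[["id", "age", phenotype]].copy()
    if phenotype in panel.count_phenotypes:
        obs[phenotype] = transform_count_phenotype(
            obs[phenotype].to_numpy(), model.log_offset
        )
    obs = obs.dropna(subset=["age", phenotype])
    cov = covariates.dropna(subset=["sex", "ethnicity"])
    frame = obs.merge(cov[["id", "sex", "ethnicity"]], on="id", how="inner")
    frame = frame.rename(columns={phenotype: "y"})
    return frame


def _design_arrays(frame: pd.DataFrame, g_by_id: pd.Series):
    """Numeric design for the fit; drops individuals with missing
    genotype and centers age on the analysed rows."""
    g = g_by_id.reindex(frame["id"]).to_numpy()
    keep = ~np.isnan(g)
    frame = frame.loc[keep]
    g = g[keep]
    agec = frame["age"].to_numpy() - frame["age"].to_numpy().mean()
    eth = frame["ethnicity"].to_numpy()
    cols = [
        np.ones(len(frame)),
        g,
        frame["sex"].to_numpy(dtype=float),
        (eth == ETHNICITIES[1]).astype(float),
        (eth == ETHNICITIES[2]).astype(float),
        agec,
        agec**2,
    ]
    X = np.column_stack(cols)
    # guard rank: drop nuisance columns constant in the analysed subset
    keep_cols = [0, 1]
    for j in range(2, X.shape[1]):
        if np.ptp(X[:, j]) > 0:
            keep_cols.append(j)
    X = X[:, keep_cols]
    y = frame["y"].to_numpy(dtype=float)
    Z = np.column_stack([np.ones(len(frame)), agec])
    clusters = frame["id"].astype("category").cat.codes.to_numpy()
    return y, X, Z, clusters


def fit_lmm(
    panel: PhenotypePanel,
    covariates: pd.DataFrame,
    coded_snp: CodedGenotype,
    phenotype: str,
    model: ModelSpec | None = None,
    start: np.ndarray | None = None,
    _frame: pd.DataFrame | None = None,
) -> FitResult:
    """Fit the mixed model for one SNP x phenotype pair.

    The SNP enters through its QC-assigned coding (additive dosage or
    dominant carrier contrast).  Raises :class:`ValueError` when fewer
    than ``model.min_individuals`` individuals remain after the
    missing-data rules.  ``_frame`` lets the scan loop reuse the
    assembled per-phenotype observation table.
    """
    model = model or ModelSpec()
    if coded_snp.samples is None:
        raise ValueError("coded_snp must carry sample ids (samples=...)")
    frame = _frame if _frame is not None else _analysis_frame(
        panel, covariates, phenotype, model
    )
    g_by_id = pd.Series(coded_snp.values, index=coded_snp.samples)
    y, X, Z, clusters = _design_arrays(frame, g_by_id)
    n_ind = len(np.unique(clusters))
    if n_ind < model.min_individuals:
        raise ValueError(
            f"only {n_ind} individuals with complete data "
            f"(minimum {model.min_individuals})"
        )
    if np.ptp(X[:, 1]) == 0:
        return FitResult(
            snp_id=coded_snp.snp_id, phenotype=phenotype,
            coding=coded_snp.coding, beta=np.nan, se=np.nan, p=np.nan,
            n_individuals=n_ind, n_observations=len(y), status="failed",
        )
    fit = _fit_arrays(y, X, Z, clusters, model, start=start)
    if fit["status"] == "failed":
        return FitResult(
            snp_id=coded_snp.snp_id, phenotype=phenotype,
            coding=coded_snp.coding, beta=np.nan, se=np.nan, p=np.nan,
            n_individuals=n_ind, n_observations=len(y), status="failed",
        )
    beta = float(fit["beta"][1])
    se = float(np.sqrt(fit["cov_beta"][1, 1]))
    z = beta / se
    p = float(min(max(2.0 * norm.sf(abs(z)), np.nextafter(0, 1)), 1.0))
    G = fit["G"]
    return FitResult(
        snp_id=coded_snp.snp_id,
        phenotype=phenotype,
        coding=coded_snp.coding,
        beta=beta,
        se=se,
        p=p,
        n_individuals=n_ind,
        n_observations=len(y),
        status=fit["status"],
        var_intercept=float(G[0, 0]),
        var_slope=float(G[1, 1]),
        cov_intercept_slope=float(G[0, 1]),
        var_residual=float(fit["s2"]),
        neg2_criterion=float(fit["criterion"]),
        theta=fit["theta"],
    )


def run_scan(
    genotypes,
    panel: PhenotypePanel,
    covariates: pd.DataFrame,
    codings: list[CodedGenotype] | None = None,
    model: ModelSpec | None = None,
    phenotypes: tuple[str, ...] | None = None,
) -> ScanResult:
    """Fit every SNP x phenotype pair of a QC-passed genotype matrix.

    Iteration order is deterministic: SNPs in genomic (row) order,
    phenotypes in the fixed panel order.  Failed fits are recorded in
    the table with ``status == "failed"``, never dropped.  Within a
    phenotype, each fit warm-starts the variance parameters from the
    previous SNP's optimum, which roughly halves the optimizer work
    without changing any optimum.
    """
    from .qc import encode_all

    model = model or ModelSpec()
    phenotypes = tuple(phenotypes or panel.phenotypes)
    if codings is None:
        codings = encode_all(genotypes)
    gene_by_snp = dict(
        zip(genotypes.snps["snp_id"], genotypes.snps["gene"])
    )
    results: dict[tuple[str, str], FitResult] = {}
    for phenotype in phenotypes:
        start = None
        frame = _analysis_frame(panel, covariates, phenotype, model)
        for coded in codings:
            fit = fit_lmm(panel, covariates, coded, phenotype,
                          model=model, start=start, _frame=frame)
            results[(coded.snp_id, phenotype)] = fit
            if fit.status == "ok" and fit.theta is not None \
                    and len(fit.theta) == 3:
                start = fit.theta
    rows = []
    for coded in codings:
        for phenotype in phenotypes:
            fit = results[(coded.snp_id, phenotype)]
            rows.append(
                {
                    "gene": gene_by_snp.get(fit.snp_id, ""),
                    "snp_id": fit.snp_id,
                    "phenotype": fit.phenotype,
                    "coding": fit.coding,
                    "beta": fit.beta,
                    "se": fit.se,
                    "p": fit.p,
                    "n_individuals": fit.n_individuals,
                    "n_observations": fit.n_observations,
                    "status": fit.status,
                    "var_intercept": fit.var_intercept,
                    "var_slope": fit.var_slope,
                    "cov_intercept_slope": fit.cov_intercept_slope,
                    "var_residual": fit.var_residual,
                }
            )
    table = pd.DataFrame(rows)
    return ScanResult(table=table, phenotypes=phenotypes, model=model)


def nominal_hits(
    scan: ScanResult, threshold: float = 0.01
) -> pd.DataFrame:
    """Rows of the scan with raw p below the nominal threshold.

    Returns an empty table (with headers) when nothing passes.
    """
    table = scan.table
    hits = table[table["p"] < threshold].copy()
    return hits.reset_index(drop=True)


def hit_grid(
    hits: pd.DataFrame, phenotypes: tuple[str, ...] = PHENOTYPES
) -> pd.DataFrame:
    """Presence/absence grid of nominal hits: one row per (gene, SNP),
    one column per phenotype, ``"x"`` marking an association."""
    index_cols = ["gene", "snp_id"]
    if hits.empty:
        return pd.DataFrame(columns=index_cols + list(phenotypes))
    grid = (
        hits.assign(mark="x")
        .pivot_table(
            index=index_cols, columns="phenotype", values="mark",
            aggfunc="first", fill_value="",
        )
        .reindex(columns=list(phenotypes), fill_value="")
        .reset_index()
    )
    grid.columns.name = None
    return grid
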