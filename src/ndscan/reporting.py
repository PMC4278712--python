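"""Descriptive statistics, standard-format I/O and report tables.

Covers pairwise LD (composite r^2 on genotype codes), the phenotype
correlation matrix, cohort summary statistics, VCF/TSV/CSV round-trip
I/O for the synthetic cohort, and the publication-style report bundle (hit
table, allele/MAF table, presence/absence grid, QC summary, LD table,
run manifest).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    COUNT_PHENOTYPES,
    MISSING,
    PHENOTYPES,
    GenotypeMatrix,
    PhenotypePanel,
)
from .lmm import ScanResult, hit_grid, nominal_hits, transform_count_phenotype
from .permutation import AdjustedResults
from .qc import QCReport

__all__ = [
    "compute_ld_r2",
    "ld_table",
    "phenotype_correlations",
    "CohortSummary",
    "cohort_summary",
    "write_vcf",
    "read_vcf",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_phenotypes_csv",
    "read_phenotypes_csv",
    "write_covariates_csv",
    "read_covariates_csv",
    "write_sidecar",
    "render_reports",
]


# --------------------------------------------------------------------------
# descriptive statistics
# --------------------------------------------------------------------------

def compute_ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Composite (phase-free) LD: squared Pearson correlation of 0/1/2
    genotype codes over individuals non-missing for both SNPs.

    Returns NaN when either vector is constant on the shared support.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_table(
    genotypes: GenotypeMatrix, snp_ids: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise r^2 for the requested SNPs (all pairs, upper triangle)."""
    ids = snp_ids if snp_ids is not None else genotypes.snp_ids
    gene_of = dict(zip(genotypes.snps["snp_id"], genotypes.snps["gene"]))
    rows = []
    for i in range(len(ids)):
        gi = genotypes.vector(ids[i])
        for j in range(i + 1, len(ids)):
            rows.append(
                {
                    "snp_a": ids[i],
                    "snp_b": ids[j],
                    "gene_a": gene_of.get(ids[i], ""),
                    "gene_b": gene_of.get(ids[j], ""),
                    "r2": compute_ld_r2(gi, genotypes.vector(ids[j])),
                }
            )
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "gene_a", "gene_b", "r2"])


def phenotype_correlations(
    panel: PhenotypePanel, level: str = "individual"
) -> pd.DataFrame:
    """Pearson correlation matrix between the phenotypes.

    ``level="individual"`` (default) correlates per-individual means
    across cycles, avoiding within-person pseudo-replication;
    ``level="observation"`` correlates raw person-cycle rows.  Count
    phenotypes are placed on the analysis (log) scale first.
    """
    obs = panel.observations.copy()
    for name in panel.count_phenotypes:
        obs[name] = transform_count_phenotype(obs[name].to_numpy())
    data = obs[["id", *panel.phenotypes]]
    if level == "individual":
        data = data.groupby("id", sort=True).mean()
    elif level == "observation":
        data = data.drop(columns="id")
    else:
        raise ValueError(f"unknown level {level!r}")
    return data[list(panel.phenotypes)].corr()


@dataclass
class CohortSummary:
    """Descriptive cohort characteristics."""

    n_individuals: int
    n_observations: int
    male_percent: float
    ethnicity_percent: dict[str, float]
    phenotype_median_iqr: dict[str, tuple[float, float]]
    age_mean: float
    age_sd: float


def cohort_summary(
    panel: PhenotypePanel, covariates: pd.DataFrame
) -> CohortSummary:
    """Medians and IQRs per phenotype plus covariate percentages.

    Quantiles use linear interpolation; IQR = Q3 - Q1.  Summaries are
    over all person-cycle observations on the raw phenotype scale.
    """
    obs = panel.observations
    eth_counts = covariates["ethnicity"].value_counts(normalize=True)
    med_iqr = {}
    for name in panel.phenotypes:
        vals = obs[name].dropna().to_numpy(dtype=float)
        q1, q2, q3 = np.percentile(vals, [25, 50, 75])
        med_iqr[name] = (float(q2), float(q3 - q1))
    return CohortSummary(
        n_individuals=len(covariates),
        n_observations=len(obs),
        male_percent=float(100.0 * covariates["sex"].mean()),
        ethnicity_percent={k: float(100.0 * v) for k, v in eth_counts.items()},
        phenotype_median_iqr=med_iqr,
        age_mean=float(obs["age"].mean()),
        age_sd=float(obs["age"].std()),
    )


# --------------------------------------------------------------------------
# file formats
# --------------------------------------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as a minimal VCFv4.2 with GT-only records;
    missing calls become ``./.``."""
    path = Path(path)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=ndscan {__version__}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                  "INFO", "FORMAT"] + list(genotypes.samples)
        fh.write("\t".join(header) + "\n")
        for i, row in genotypes.snps.iterrows():
            calls = [gt_strings[int(g)] for g in genotypes.genotypes[i]]
            fields = [
                str(row.get("chrom", "1")), str(row.get("pos", i + 1)),
                row["snp_id"], str(row.get("ref", "A")),
                str(row.get("alt", "G")), ".", "PASS", ".", "GT",
            ] + calls
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a GT-only VCF back into a :class:`GenotypeMatrix`."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    geno_rows, meta_rows = [], []
    for variant in vcf:
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        codes = np.asarray(variant.gt_types)
        g = np.select(
            [codes == 0, codes == 1, codes == 3], [0, 1, 2], default=MISSING
        ).astype(np.int8)
        geno_rows.append(g)
        meta_rows.append(
            {
                "snp_id": variant.ID,
                "gene": "",
                "chrom": variant.CHROM,
                "pos": variant.POS,
                "ref": variant.REF,
                "alt": variant.ALT[0] if variant.ALT else ".",
            }
        )
    return GenotypeMatrix(
        genotypes=np.asarray(geno_rows, dtype=np.int8),
        snps=pd.DataFrame(meta_rows),
        samples=samples,
    )


def write_genotype_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """SNP x individual TSV (values 0/1/2/NA) with metadata columns."""
    g = genotypes.genotypes.astype(object)
    g[genotypes.genotypes == MISSING] = "NA"
    body = pd.DataFrame(g, columns=genotypes.samples)
    out = pd.concat([genotypes.snps.reset_index(drop=True), body], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = [c for c in ("snp_id", "gene", "chrom", "pos", "ref", "alt",
                             "injected") if c in df.columns]
    samples = [c for c in df.columns if c not in meta_cols]
    g = df[samples].apply(pd.to_numeric, errors="coerce").to_numpy()
    g = np.where(np.isnan(g), MISSING, g).astype(np.int8)
    return GenotypeMatrix(genotypes=g, snps=df[meta_cols], samples=samples)


def write_phenotypes_csv(
    panel: PhenotypePanel, covariates: pd.DataFrame, path: str | Path
) -> None:
    """Long-format CSV: id, cycle, age, sex, ethnicity, phenotypes."""
    out = panel.observations.merge(
        covariates[["id", "sex", "ethnicity"]], on="id", how="left"
    )
    cols = ["id", "cycle", "age", "sex", "ethnicity", *panel.phenotypes]
    out[cols].to_csv(path, index=False)


def read_phenotypes_csv(
    path: str | Path,
    phenotypes: tuple[str, ...] = PHENOTYPES,
    count_phenotypes: tuple[str, ...] = COUNT_PHENOTYPES,
) -> tuple[PhenotypePanel, pd.DataFrame]:
    df = pd.read_csv(path)
    panel = PhenotypePanel(
        observations=df[["id", "cycle", "age", *phenotypes]].copy(),
        phenotypes=phenotypes,
        count_phenotypes=count_phenotypes,
    )
    covariates = (
        df[["id", "sex", "ethnicity"]].drop_duplicates("id").reset_index(drop=True)
    )
    return panel, covariates


def write_covariates_csv(covariates: pd.DataFrame, path: str | Path) -> None:
    covariates.to_csv(path, index=False)


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_sidecar(parameters: dict, path: str | Path) -> None:
    """YAML sidecar recording generator/run parameters and seeds."""
    with open(path, "w") as fh:
        yaml.safe_dump(parameters, fh, sort_keys=True)


# --------------------------------------------------------------------------
# report bundle
# --------------------------------------------------------------------------

def render_reports(
    out_dir: str | Path,
    scan: ScanResult,
    adjusted: AdjustedResults | None = None,
    qc_report: QCReport | None = None,
    genotypes: GenotypeMatrix | None = None,
    summary: CohortSummary | None = None,
    manifest: dict | None = None,
    threshold: float = 0.01,
) -> dict[str, Path]:
    """Write the report bundle as TSV/JSON files.

    Contents: the nominal hit table with every available p-value
    column, a minor/major-allele MAF table for hit SNPs, the
    presence/absence grid of hits, the QC summary, pairwise LD among
    hit SNPs, a cohort summary and a run manifest.  Output is
    deterministic: rerunning with identical inputs reproduces the
    bundle byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    source = adjusted.table if adjusted is not None else scan.table
    scan_like = ScanResult(table=source, phenotypes=scan.phenotypes,
                           model=scan.model)
    hits = nominal_hits(scan_like, threshold=threshold)

    def emit(name: str, df: pd.DataFrame) -> None:
        p = out_dir / name
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written[name] = p

    emit("scan_table.tsv", source)
    emit("hit_table.tsv", hits)
    emit("hit_grid.tsv", hit_grid(hits, scan.phenotypes))

    if genotypes is not None and not hits.empty:
        hit_snps = sorted(hits["snp_id"].unique())
        present = [s for s in hit_snps if s in set(genotypes.snp_ids)]
        maf_rows = []
        from .qc import compute_maf

        for snp_id in present:
            row = genotypes.snps.loc[
                genotypes.snps["snp_id"] == snp_id
            ].iloc[0]
            g = genotypes.vector(snp_id)
            obs = g[g != MISSING]
            f_alt = obs.sum() / (2 * obs.size) if obs.size else float("nan")
            minor, major = (
                (row["alt"], row["ref"]) if f_alt <= 0.5 else (row["ref"], row["alt"])
            )
            maf_rows.append(
                {
                    "gene": row["gene"],
                    "snp_id": snp_id,
                    "minor_allele": minor,
                    "major_allele": major,
                    "maf": compute_maf(g),
                }
            )
        emit("hit_maf_table.tsv", pd.DataFrame(
            maf_rows, columns=["gene", "snp_id", "minor_allele",
                               "major_allele", "maf"]))
        if len(present) > 1:
            emit("hit_ld_table.tsv", ld_table(genotypes, present))

    if qc_report is not None:
        emit("qc_per_snp.tsv", qc_report.per_snp)
        p = out_dir / "qc_summary.json"
        with open(p, "w") as fh:
            json.dump(qc_report.summary(), fh, indent=2, sort_keys=True)
        written["qc_summary.json"] = p

    if summary is not None:
        p = out_dir / "cohort_summary.json"
        with open(p, "w") as fh:
            json.dump(asdict(summary), fh, indent=2, sort_keys=True)
        written["cohort_summary.json"] = p

    manifest = dict(manifest or {})
    manifest.setdefault("ndscan_version", __version__)
    manifest["n_tests"] = int(scan.n_tests)
    manifest["nominal_threshold"] = threshold
    if adjusted is not None:
        manifest["alpha_star"] = adjusted.alpha_star
        manifest["fwer_alpha"] = adjusted.fwer_alpha
        manifest["n_permutations"] = adjusted.scheme.n_permutations
        manifest["permutation_seed"] = adjusted.scheme.seed
    p = out_dir / "manifest.json"
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written["manifest.json"] = p

    lines = [
        f"ndscan report ({scan.n_tests} tests, "
        f"{len(hits)} nominal hits at p < {threshold})",
    ]
    if adjusted is not None:
        lines.append(
            f"maxT family-wise raw-p threshold alpha* = "
            f"{adjusted.alpha_star:.3g} "
            f"({adjusted.scheme.n_permutations} permutations)"
        )
    p = out_dir / "summary.txt"
    with open(p, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    written["summary.txt"] = p
    return written
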