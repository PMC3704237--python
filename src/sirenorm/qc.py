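"""Genotype quality control for the sire panel.

Filtering mirrors standard GWAS practice for 50k-chip data: individuals
with more than 10% missing genotypes are removed first, then SNPs with
minor allele frequency below 3%, call rate below 90%, Hardy-Weinberg
deviation at P < 0.001, unknown genomic position, or a sex-chromosome
label are excluded.  Threshold comparisons are strict.  Sporadic missing
calls that survive QC are imputed to the modal genotype class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, QcError
from .genotypes import MISSING, SEX_CHROMOSOMES, GenotypeMatrix


@dataclass
class QcReport:
    """Per-SNP and per-individual QC statistics with pass flags.

    ``snp_table`` columns: snp_id, maf, call_rate, hwe_p, position_known,
    autosomal, pass, reasons (';'-joined failure reasons, empty if pass).
    ``individual_table`` columns: individual_id, missingness, pass.
    Either table may be empty if the corresponding filter was not run.
    """

    snp_table: pd.DataFrame
    individual_table: pd.DataFrame


def compute_maf(calls) -> float:
    """Minor allele frequency from dosage calls for a single SNP."""
    calls = np.asarray(calls)
    obs = calls[calls != MISSING]
    if obs.size == 0:
        raise DegenerateDataError("all calls missing; allele frequency undefined")
    f = obs.sum() / (2.0 * obs.size)
    return float(min(f, 1.0 - f))


def compute_call_rate(calls) -> float:
    """Fraction of non-missing calls for a single SNP."""
    calls = np.asarray(calls)
    if calls.size == 0:
        raise ValueError("empty call vector")
    return float((calls != MISSING).mean())


def hwe_test(n_hom_counted: int, n_het: int, n_hom_other: int) -> float:
    """1-df chi-square Hardy-Weinberg goodness-of-fit p-value.

    Expected counts are n*p^2, 2n*p*q, n*q^2 with the allele frequency
    estimated from the genotype counts.  Monomorphic SNPs return 1.
    """
    n = n_hom_counted + n_het + n_hom_other
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    p = (2 * n_hom_counted + n_het) / (2.0 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_hom_counted, n_het, n_hom_other], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def individual_missingness(matrix: GenotypeMatrix) -> np.ndarray:
    if matrix.n_snps == 0:
        return np.zeros(matrix.n_individuals)
    return (matrix.calls == MISSING).mean(axis=1)


def filter_individuals(matrix: GenotypeMatrix, max_missing: float = 0.10):
    """Remove individuals with missingness strictly above ``max_missing``.

    Returns ``(filtered_matrix, QcReport)``; survivor order is preserved.
    Raises :class:`QcError` if nobody survives.
    """
    miss = individual_missingness(matrix)
    keep = miss <= max_missing
    report = QcReport(
        snp_table=pd.DataFrame(),
        individual_table=pd.DataFrame(
            {"individual_id": matrix.individuals, "missingness": miss, "pass": keep}
        ),
    )
    if not keep.any():
        raise QcError("all individuals exceed the missingness threshold")
    filtered = GenotypeMatrix(matrix.individuals[keep], matrix.snps.copy(), matrix.calls[keep])
    return filtered, report


def snp_statistics(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP MAF, call rate and HWE p-value on the current individuals."""
    calls = matrix.calls
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    call_rate = n_obs / matrix.n_individuals if matrix.n_individuals else np.zeros(matrix.n_snps)

    dose = np.where(obs, calls, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = dose.sum(axis=0) / (2.0 * n_obs)
    maf = np.minimum(f, 1.0 - f)

    n_hom2 = ((calls == 2)).sum(axis=0)
    n_het = ((calls == 1)).sum(axis=0)
    n_hom0 = ((calls == 0)).sum(axis=0)
    hwe_p = np.ones(matrix.n_snps)
    for k in range(matrix.n_snps):
        if n_obs[k] > 0:
            hwe_p[k] = hwe_test(int(n_hom2[k]), int(n_het[k]), int(n_hom0[k]))
        else:
            hwe_p[k] = np.nan
            maf[k] = np.nan
    snps = matrix.snps
    return pd.DataFrame(
        {
            "snp_id": snps["snp_id"],
            "maf": maf,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
            "position_known": snps["pos"].to_numpy() > 0,
            "autosomal": ~snps["chrom"].astype(str).isin(SEX_CHROMOSOMES),
        }
    )


def filter_snps(
    matrix: GenotypeMatrix,
    maf_min: float = 0.03,
    call_rate_min: float = 0.90,
    hwe_alpha: float = 0.001,
):
    """Apply the SNP filters; returns ``(filtered_matrix, QcReport)``.

    A SNP is removed iff at least one failure reason is recorded:
    ``low_maf`` (maf < maf_min), ``low_call_rate`` (call rate <
    call_rate_min), ``hwe`` (HWE p < hwe_alpha), ``unknown_position``
    (position 0) or ``sex_chromosome``.  Setting a numeric threshold to
    0 disables that filter.  Individual filtering is expected to have
    been applied first; statistics are computed on the surviving
    individuals.
    """
    table = snp_statistics(matrix)
    maf = table["maf"].to_numpy()
    fail = {
        "low_maf": np.where(np.isnan(maf), maf_min > 0, maf < maf_min),
        "low_call_rate": table["call_rate"].to_numpy() < call_rate_min,
        "hwe": np.where(np.isnan(table["hwe_p"].to_numpy()), False, table["hwe_p"].to_numpy() < hwe_alpha),
        "unknown_position": ~table["position_known"].to_numpy(),
        "sex_chromosome": ~table["autosomal"].to_numpy(),
    }
    reasons = []
    for k in range(len(table)):
        reasons.append(";".join(name for name, mask in fail.items() if mask[k]))
    table["reasons"] = reasons
    table["pass"] = np.array([r == "" for r in reasons])
    keep = table["pass"].to_numpy()
    report = QcReport(snp_table=table, individual_table=pd.DataFrame())
    return matrix.subset_snps(keep), report


def impute_sporadic(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call by the SNP's modal genotype class.

    Ties among modal classes are broken toward the class nearest the
    expected dosage 2f (f = counted-allele frequency among observed
    calls), then toward the smaller class.  Non-missing calls and the
    counted-allele designation are never changed.
    """
    out = matrix.copy()
    calls = out.calls
    for k in np.flatnonzero((calls == MISSING).any(axis=0)):
        col = calls[:, k]
        obs = col[col != MISSING]
        if obs.size == 0:
            raise DegenerateDataError(
                f"SNP {out.snps.snp_id[k]} has no observed calls; should have failed call-rate QC"
            )
        counts = np.bincount(obs, minlength=3)
        best = counts.max()
        modal = [g for g in (0, 1, 2) if counts[g] == best]
        expected = obs.sum() / obs.size  # = 2f
        winner = min(modal, key=lambda g: (abs(g - expected), g))
        col[col == MISSING] = winner
    return out


def run_qc(
    matrix: GenotypeMatrix,
    max_missing: float = 0.10,
    maf_min: float = 0.03,
    call_rate_min: float = 0.90,
    hwe_alpha: float = 0.001,
    impute: bool = True,
):
    """Full QC pipeline: individuals, then SNPs, then modal imputation.

    Returns ``(matrix, QcReport)`` with both report tables populated.
    """
    matrix, ind_report = filter_individuals(matrix, max_missing)
    matrix, snp_report = filter_snps(matrix, maf_min, call_rate_min, hwe_alpha)
    if impute:
        matrix = impute_sporadic(matrix)
    return matrix, QcReport(snp_table=snp_report.snp_table, individual_table=ind_report.individual_table)
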