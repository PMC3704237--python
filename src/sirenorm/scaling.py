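"""Observed-scale vs log-scale decomposition of GxE at validated SNPs.

Genotype-by-environment interaction that only stretches or shrinks the
spread of genotype means across environments ("scaling" GxE) can be
removed by a monotone transformation of the yields; interaction that
re-ranks genotypes cannot.  This module runs the full reaction-norm +
association pipeline twice — on observed yields with the full model,
and on natural-log yields with the reduced model (no daughter slope,
homogeneous residual) — using the *same* discovery/validation split,
and classifies every SNP tested for environmental sensitivity:

==================  =====================================
observed_only       effect removable by the log transform
both                persistent (not pure scaling)
log_only            emerges only on the log scale
neither             unconfirmed on either scale
==================  =====================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import (
    DISCOVERY_ALPHA,
    VALIDATION_ALPHA,
    SplitPlan,
    run_gwas,
    validate_snps,
)
from .genotypes import GenotypeMatrix
from .kinship import RelationshipMatrix
from .reaction_norm import ReactionNormFit, fit_reaction_norm, slope_variance_lrt


def log_transform_records(records: pd.DataFrame, trait: str = "cy") -> pd.DataFrame:
    """Natural-log transform of the yield column; positivity is mandatory.

    Returns a copy with ``trait`` replaced by its log and the metadata
    column ``transform`` set to 'ln'.  Nonpositive yields raise a hard
    error listing the offending rows.
    """
    y = records[trait].to_numpy(dtype=float)
    bad = np.flatnonzero(~(y > 0))
    if bad.size:
        raise ValueError(
            f"log transform undefined: {bad.size} nonpositive yields at rows {bad[:10].tolist()}"
        )
    out = records.copy()
    out[trait] = np.log(y)
    out.attrs["transform"] = "ln"
    return out


@dataclass
class ScaleComparison:
    """Joined ES validation outcomes on both scales plus classifications."""

    table: pd.DataFrame
    fit_observed: ReactionNormFit
    fit_log: ReactionNormFit
    gwas_observed: pd.DataFrame
    gwas_log: pd.DataFrame
    validation_observed: pd.DataFrame
    validation_log: pd.DataFrame
    obs_slope_lrt: dict
    log_slope_lrt: dict


def _classify(obs: bool, log: bool) -> str:
    if obs and log:
        return "both"
    if obs:
        return "observed_only"
    if log:
        return "log_only"
    return "neither"


def run_scale_comparison(
    records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    relationship: RelationshipMatrix,
    split: SplitPlan,
    trait: str = "cy",
    discovery_alpha: float = DISCOVERY_ALPHA,
    validation_alpha: float = VALIDATION_ALPHA,
    slope_support_alpha: float = 0.05,
) -> ScaleComparison:
    """Side-by-side observed- and log-scale ES pipelines on one split.

    The comparison table has one row per SNP tested for ES on either
    scale: ``snp_id, validated_obs_es, validated_log_es,
    classification, beta_obs, beta_log, beta_obs_sd, beta_log_sd`` —
    the ``_sd`` columns standardise the validation-set effects by the
    fitted sire slope SD of their own scale, making them comparable
    across scales.

    A scale's ES association stage only runs when that scale's fitted
    sire slope variance is statistically supported (REML LRT against
    the no-slope model at ``slope_support_alpha``).  When a fit cannot
    distinguish the slope variance from zero its slope BLUPs carry no
    slope information — they collapse to a multiple of the intercept
    estimates through the fitted covariance — so an "ES" scan on them
    would silently test general production instead; such a scale
    contributes an empty validated-ES set.
    """
    from .errors import ConvergenceError

    def fit_both(recs, mode):
        try:
            return fit_reaction_norm(recs, mode=mode, trait=trait, compute_se=False)
        except ConvergenceError as err:
            if err.best_fit is not None:
                return err.best_fit
            raise

    fit_obs, est_obs = fit_both(records, "heterogeneous_slope_daughter")
    log_records = log_transform_records(records, trait)
    fit_log, est_log = fit_both(log_records, "homogeneous_intercept_daughter")
    lrt_obs = slope_variance_lrt(
        records, mode="heterogeneous_slope_daughter", trait=trait, full=fit_obs
    )
    lrt_log = slope_variance_lrt(
        log_records, mode="homogeneous_intercept_daughter", trait=trait, full=fit_log
    )

    empty_gwas = pd.DataFrame(
        columns=["snp_id", "chrom", "pos", "component", "freq", "beta", "se", "z", "p",
                 "failed", "significant", "q"]
    )
    empty_conf = pd.DataFrame(
        columns=["snp_id", "chrom", "pos", "component", "beta_discovery", "p_discovery",
                 "beta_validation", "se_validation", "p_validation", "validated"]
    )
    results = {}
    for label, est, fit, lrt in (
        ("obs", est_obs, fit_obs, lrt_obs),
        ("log", est_log, fit_log, lrt_log),
    ):
        if lrt["p_value"] > slope_support_alpha:
            results[label] = (empty_gwas.copy(), empty_conf.copy(), fit)
            continue
        disc = est[est["sire_id"].astype(str).isin(set(map(str, split.discovery)))]
        valid = est[est["sire_id"].astype(str).isin(set(map(str, split.validation)))]
        gwas = run_gwas(disc, genotypes, relationship, component="es", alpha=discovery_alpha)
        confirmed = validate_snps(
            gwas, valid, genotypes, relationship, component="es", alpha=validation_alpha
        )
        results[label] = (gwas, confirmed, fit)

    gwas_obs, conf_obs, _ = results["obs"]
    gwas_log, conf_log, _ = results["log"]
    val_obs = set(conf_obs.loc[conf_obs["validated"], "snp_id"]) if len(conf_obs) else set()
    val_log = set(conf_log.loc[conf_log["validated"], "snp_id"]) if len(conf_log) else set()
    tested = sorted(set(conf_obs["snp_id"]) | set(conf_log["snp_id"]))

    beta_obs = conf_obs.set_index("snp_id")["beta_validation"] if len(conf_obs) else pd.Series(dtype=float)
    beta_log = conf_log.set_index("snp_id")["beta_validation"] if len(conf_log) else pd.Series(dtype=float)
    sd_obs = np.sqrt(fit_obs.sigma_s1_sq) if fit_obs.sigma_s1_sq > 0 else np.nan
    sd_log = np.sqrt(fit_log.sigma_s1_sq) if fit_log.sigma_s1_sq > 0 else np.nan

    rows = []
    for snp in tested:
        o = snp in val_obs
        l = snp in val_log
        bo = float(beta_obs.get(snp, np.nan))
        bl = float(beta_log.get(snp, np.nan))
        rows.append(
            {
                "snp_id": snp,
                "validated_obs_es": o,
                "validated_log_es": l,
                "classification": _classify(o, l),
                "beta_obs": bo,
                "beta_log": bl,
                "beta_obs_sd": bo / sd_obs if np.isfinite(sd_obs) else np.nan,
                "beta_log_sd": bl / sd_log if np.isfinite(sd_log) else np.nan,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "snp_id", "validated_obs_es", "validated_log_es", "classification",
            "beta_obs", "beta_log", "beta_obs_sd", "beta_log_sd",
        ],
    )
    return ScaleComparison(
        table=table,
        fit_observed=fit_obs,
        fit_log=fit_log,
        gwas_observed=gwas_obs,
        gwas_log=gwas_log,
        validation_observed=conf_obs,
        validation_log=conf_log,
        obs_slope_lrt=lrt_obs,
        log_slope_lrt=lrt_log,
    )
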