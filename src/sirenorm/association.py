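"""Kinship-controlled single-SNP association on sire GP/ES estimates.

For each SNP k the model is

    s_hat_j = mu + b_k * x_jk + u_j + e_j,

where s_hat_j is a sire's BLUP estimate for general production (GP,
reaction-norm intercept) or environmental sensitivity (ES, slope),
x_jk counts copies of the SNP's more frequent allele, u ~ N(0, A*sg2)
is a polygenic sire effect with the numerator relationship matrix A,
and e ~ N(0, I*se2).  A single eigendecomposition of A reduces every
SNP to a one-dimensional REML profile over the variance ratio plus a
weighted regression, the standard mixed-model association device.
P-values are Wald tests with a normal reference; false-discovery-rate
q-values follow Storey's procedure.  Significant SNPs (discovery
P < 0.001) are confirmed in an independent validation sample when the
validation P < 0.01 and the effect signs agree; validation-set
estimates are the reported effect sizes, since discovery-set estimates
are upward-biased at selected loci (Beavis effect).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateDataError
from .genotypes import GenotypeMatrix
from .kinship import RelationshipMatrix

DISCOVERY_ALPHA = 0.001
VALIDATION_ALPHA = 0.01


# ---------------------------------------------------------------------------
# discovery/validation split
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    """Disjoint discovery/validation partition of the sire ids."""

    discovery: list
    validation: list
    seed: int

    def __post_init__(self):
        overlap = set(self.discovery) & set(self.validation)
        if overlap:
            raise ValueError(f"split sets overlap: {sorted(overlap)[:5]}")


def split_sires(ids, n_validation: int = 500, seed: int = 0) -> SplitPlan:
    """Uniformly random discovery/validation partition, reproducible by seed."""
    ids = list(ids)
    if n_validation >= len(ids):
        raise ValueError(f"n_validation={n_validation} must be smaller than n={len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    validation = [ids[i] for i in sorted(perm[:n_validation])]
    discovery = [ids[i] for i in sorted(perm[n_validation:])]
    return SplitPlan(discovery=discovery, validation=validation, seed=seed)


# ---------------------------------------------------------------------------
# per-SNP mixed linear model via eigendecomposition of A
# ---------------------------------------------------------------------------


class KinshipOperator:
    """Cached eigendecomposition of A over a fixed sire order."""

    def __init__(self, relationship: RelationshipMatrix, ids):
        sub = relationship.restrict(ids)
        vals, vecs = np.linalg.eigh(sub.values)
        if vals.min() < -1e-8 * max(1.0, vals.max()):
            raise np.linalg.LinAlgError("relationship matrix is not positive semidefinite")
        self.ids = list(sub.ids)
        self.eigenvalues = np.clip(vals, 0.0, None)
        self.eigenvectors = vecs

    def rotate(self, arr):
        return self.eigenvectors.T @ arr


@dataclass
class SnpFit:
    beta: float
    se: float
    z: float
    p: float
    sigma_g_sq: float
    sigma_e_sq: float
    gamma: float  # variance ratio sigma_g_sq / sigma_e_sq
    loglik: float


def _profile_reml(y_rot, x_rot, ones_rot, lam, log_gamma):
    """Profiled restricted log-likelihood at a fixed variance ratio.

    Returns (loglik, beta, se_unscaled..., sigma_e2).  All inputs live in
    the eigenbasis of A, so the covariance is diagonal.
    """
    gamma = np.exp(log_gamma)
    w = 1.0 / (gamma * lam + 1.0)
    n = y_rot.size
    p = 2
    a11 = np.sum(w * ones_rot * ones_rot)
    a12 = np.sum(w * ones_rot * x_rot)
    a22 = np.sum(w * x_rot * x_rot)
    b1 = np.sum(w * ones_rot * y_rot)
    b2 = np.sum(w * x_rot * y_rot)
    det = a11 * a22 - a12 * a12
    if det <= 0 or not np.isfinite(det):
        return -np.inf, 0.0, np.inf, 0.0
    beta0 = (a22 * b1 - a12 * b2) / det
    beta1 = (a11 * b2 - a12 * b1) / det
    resid = y_rot - beta0 * ones_rot - beta1 * x_rot
    rss = np.sum(w * resid * resid)
    sigma_e2 = rss / (n - p)
    if sigma_e2 <= 0:
        return -np.inf, beta1, np.inf, sigma_e2
    ll = -0.5 * (
        (n - p) * (np.log(2 * np.pi * sigma_e2) + 1.0)
        - np.sum(np.log(w))
        + np.log(det)
    )
    var_b1 = sigma_e2 * a11 / det
    return ll, beta1, np.sqrt(var_b1), sigma_e2


def fit_snp_mlm(y, x, operator_or_A, ids=None) -> SnpFit:
    """One-SNP mixed-model association fit.

    ``operator_or_A`` is either a prepared :class:`KinshipOperator` or a
    :class:`RelationshipMatrix` (with ``ids`` giving the sire order of
    ``y`` and ``x``).  The variance ratio is profiled by bounded scalar
    optimisation of the restricted likelihood, with the no-polygenic
    boundary included.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDataError("monomorphic SNP: regression effect undefined")
    if isinstance(operator_or_A, KinshipOperator):
        op = operator_or_A
    else:
        op = KinshipOperator(operator_or_A, ids if ids is not None else operator_or_A.ids)
    lam = op.eigenvalues
    y_rot = op.rotate(y)
    x_rot = op.rotate(x)
    ones_rot = op.rotate(np.ones_like(y))
    return _fit_rotated(y_rot, x_rot, ones_rot, lam)


def _fit_rotated(y_rot, x_rot, ones_rot, lam) -> SnpFit:
    def negll(log_gamma):
        return -_profile_reml(y_rot, x_rot, ones_rot, lam, log_gamma)[0]

    # coarse grid then local refinement; include the gamma -> 0 boundary.
    # the search domain [-16, 16] in log gamma covers every practically
    # distinguishable variance ratio
    grid = np.linspace(-16.0, 16.0, 33)
    values = np.array([negll(g) for g in grid])
    i = int(np.argmin(values))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    best_lg = res.x if res.fun <= values[i] else grid[i]
    ll, beta, se, sigma_e2 = _profile_reml(y_rot, x_rot, ones_rot, lam, best_lg)
    ll0, beta0_, se0, sig0 = _profile_reml(y_rot, x_rot, ones_rot, lam, -30.0)
    if ll0 >= ll:  # no-polygenic boundary wins
        ll, beta, se, sigma_e2, best_lg = ll0, beta0_, se0, sig0, -np.inf
    gamma = float(np.exp(best_lg)) if np.isfinite(best_lg) else 0.0
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return SnpFit(
        beta=float(beta),
        se=float(se),
        z=float(z),
        p=float(p),
        sigma_g_sq=float(gamma * sigma_e2),
        sigma_e_sq=float(sigma_e2),
        gamma=gamma,
        loglik=float(ll),
    )


def run_gwas(
    estimates: pd.DataFrame,
    genotypes: GenotypeMatrix,
    relationship: RelationshipMatrix,
    component: str = "gp",
    alpha: float = DISCOVERY_ALPHA,
    add_qvalues: bool = True,
) -> pd.DataFrame:
    """Per-SNP mixed-model scan of one trait component over all SNPs.

    ``estimates`` must carry ``sire_id`` and the ``component`` column
    ('gp' or 'es').  Returns one row per SNP: snp_id, chrom, pos,
    component, freq, beta, se, z, p, q, significant, failed.  SNPs that
    cannot be fitted (monomorphic) are flagged, not dropped.
    """
    ids = estimates["sire_id"].astype(str).tolist()
    geno = genotypes.subset_individuals(ids)
    y = estimates[component].to_numpy(dtype=float)
    op = KinshipOperator(relationship, ids)
    lam = op.eigenvalues
    x_all = geno.calls.astype(float)
    if np.any(x_all < 0):
        raise DegenerateDataError("genotypes contain missing calls; impute before association")
    y_rot = op.rotate(y)
    ones_rot = op.rotate(np.ones_like(y))
    x_rot_all = op.eigenvectors.T @ x_all

    rows = []
    freqs = x_all.mean(axis=0) / 2.0
    for k in range(geno.n_snps):
        x = x_all[:, k]
        if np.ptp(x) == 0:
            rows.append((np.nan, np.nan, np.nan, np.nan, True))
            continue
        fit = _fit_rotated(y_rot, x_rot_all[:, k], ones_rot, lam)
        rows.append((fit.beta, fit.se, fit.z, fit.p, False))
    arr = np.array(rows, dtype=float)
    table = pd.DataFrame(
        {
            "snp_id": geno.snps["snp_id"],
            "chrom": geno.snps["chrom"],
            "pos": geno.snps["pos"],
            "component": component,
            "freq": freqs,
            "beta": arr[:, 0],
            "se": arr[:, 1],
            "z": arr[:, 2],
            "p": arr[:, 3],
            "failed": arr[:, 4].astype(bool),
        }
    )
    table["significant"] = (table["p"] < alpha).fillna(False)
    if add_qvalues:
        ok = ~table["failed"]
        q = np.full(len(table), np.nan)
        if ok.any():
            q[ok.to_numpy()] = qvalues(table.loc[ok, "p"].to_numpy())
        table["q"] = q
    return table


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------


def estimate_pi0(pvals: np.ndarray) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed on the
    grid 0.05, 0.10, ..., 0.95 and smoothed by a natural cubic fit; the
    smoother's value at the largest lambda, clipped to (0, 1], is
    returned.  Degenerate inputs (all p tiny) fall back to 1 with a
    warning.
    """
    pvals = np.asarray(pvals, dtype=float)
    m = pvals.size
    lam = np.arange(0.05, 0.951, 0.05)
    pi0_lam = np.array([(pvals > l).sum() / (m * (1.0 - l)) for l in lam])
    if np.all(pi0_lam == 0):
        warnings.warn("all p-values small; pi0 set to 1", stacklevel=2)
        return 1.0
    coeffs = np.polyfit(lam, pi0_lam, deg=3)
    pi0 = float(np.polyval(coeffs, lam[-1]))
    if not np.isfinite(pi0) or pi0 <= 0:
        warnings.warn("degenerate pi0 smoother; pi0 set to 1", stacklevel=2)
        return 1.0
    return min(pi0, 1.0)


def qvalues(pvals, pi0: float | None = None) -> np.ndarray:
    """Storey FDR q-values; with ``pi0=1`` equals Benjamini-Hochberg.

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j over the ascending order
    statistics, mapped back to the input order.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pvals.size
    if pi0 is None:
        pi0 = estimate_pi0(pvals)
    order = np.argsort(pvals, kind="stable")
    ranked = pi0 * m * pvals[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def manhattan_points(gwas_table: pd.DataFrame) -> pd.DataFrame:
    """-log10(p) per genomic position, for Manhattan-style plotting.

    Returns a DataFrame (chrom, pos, neg_log10_p, significant) sorted by
    chromosome and position; plotting itself is left to the caller.
    """
    ok = gwas_table[~gwas_table["failed"]].copy()
    ok["neg_log10_p"] = -np.log10(np.clip(ok["p"].to_numpy(dtype=float), 1e-300, 1.0))
    cols = ["chrom", "pos", "neg_log10_p", "significant"]
    key = pd.to_numeric(ok["chrom"], errors="coerce").fillna(np.inf)
    return ok.assign(_key=key).sort_values(["_key", "pos"], kind="stable")[cols].reset_index(drop=True)


def estimate_fdr_at_threshold(gwas_table: pd.DataFrame, p_threshold: float = DISCOVERY_ALPHA) -> float:
    """q-value of the weakest significant SNP (largest p below threshold).

    Estimates the proportion of false positives among the significant
    associations.  Raises if no SNP is significant.
    """
    sig = gwas_table[(gwas_table["p"] < p_threshold) & ~gwas_table["failed"]]
    if sig.empty:
        raise DegenerateDataError(f"no SNP with p < {p_threshold}; FDR at threshold undefined")
    row = sig.loc[sig["p"].idxmax()]
    return float(row["q"])


# ---------------------------------------------------------------------------
# validation protocol
# ---------------------------------------------------------------------------


def validate_snps(
    discovery: pd.DataFrame,
    validation_estimates: pd.DataFrame,
    genotypes: GenotypeMatrix,
    relationship: RelationshipMatrix,
    component: str = "gp",
    alpha: float = VALIDATION_ALPHA,
) -> pd.DataFrame:
    """Confirm discovery-significant SNPs in the validation sample.

    Each SNP significant in ``discovery`` is refitted on the validation
    sires only; it is validated iff the validation p-value is below
    ``alpha`` and the two effect estimates share the same strict sign.
    Returns one row per tested SNP with both fits; the validation
    estimates are the reporting estimates.  An empty discovery set
    yields an empty result.
    """
    sig = discovery[discovery["significant"] & ~discovery["failed"]]
    ids = validation_estimates["sire_id"].astype(str).tolist()
    missing = set(ids) - set(str(i) for i in genotypes.individuals)
    if missing:
        raise KeyError(f"validation sires lack genotypes: {sorted(missing)[:5]}")
    columns = [
        "snp_id", "chrom", "pos", "component", "beta_discovery", "p_discovery",
        "beta_validation", "se_validation", "p_validation", "validated",
    ]
    if sig.empty:
        return pd.DataFrame(columns=columns)
    geno = genotypes.subset_individuals(ids)
    op = KinshipOperator(relationship, ids)
    y = validation_estimates[component].to_numpy(dtype=float)
    y_rot = op.rotate(y)
    ones_rot = op.rotate(np.ones(len(ids)))
    snp_pos = {s: i for i, s in enumerate(geno.snps["snp_id"])}
    out = []
    for row in sig.itertuples(index=False):
        k = snp_pos[row.snp_id]
        x = geno.calls[:, k].astype(float)
        if np.ptp(x) == 0:
            out.append((row.snp_id, row.chrom, row.pos, component, row.beta, row.p,
                        np.nan, np.nan, np.nan, False))
            continue
        fit = _fit_rotated(y_rot, op.rotate(x), ones_rot, op.eigenvalues)
        same_sign = row.beta * fit.beta > 0  # a zero estimate never validates
        validated = bool(fit.p < alpha and same_sign)
        out.append((row.snp_id, row.chrom, row.pos, component, row.beta, row.p,
                    fit.beta, fit.se, fit.p, validated))
    return pd.DataFrame(out, columns=columns)
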