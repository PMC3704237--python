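"""Synthetic progeny-test data with known reaction-norm architecture.

Emulates a daughter design: genotyped sires, each with many ungenotyped
daughters whose corrected yields are recorded once each at a
herd-test-day (HTD) whose quality is a standard-normal environmental
value.  Two generative modes are supported:

``additive``
    the reaction-norm model itself, with correlated sire
    intercept/slope effects, correlated daughter intercept/slope
    effects and residual variance heterogeneous over environment
    deciles — slope variance here is genuine genotype-by-environment
    interaction that no monotone transformation removes entirely;
``multiplicative``
    yields are the exponential of a log-scale model with *no* slope
    terms, so all interaction on the observed scale is pure scaling
    (genotype spread changes across environments without re-ranking)
    and is removable by the log transformation.

Default variance components follow German Holstein protein yield
(grams per test day): sire intercept variance 2379.37, slope variance
17.02, intercept-slope correlation 0.79.  Daughter and residual
defaults are moderate because the simulator emulates yields already
corrected by a routine evaluation; see docs/methods.md.

Every dataset retains full ground truth (true effects, QTL content,
environments, the config) for recovery tests.  All randomness flows
from a single integer seed through named substreams, so stage outputs
are reproducible bit for bit and stable when other stages' parameters
change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import assign_residual_classes
from .errors import ConfigurationError, SimulationError
from .genotypes import MISSING, GenotypeMatrix

#: substream labels -> fixed offsets mixed into the seed sequence
_STREAMS = {"genotypes": 1, "pedigree": 2, "sire_effects": 3, "records": 4, "missing": 5}

#: representative German Holstein protein-yield sire components
#: (grams^2 per test day; intercept variance, slope variance, correlation)
PROTEIN_SIRE_COMPONENTS = (2379.37, 17.02, 0.79)


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of a synthetic progeny-test study."""

    n_sires: int = 500
    daughters_per_sire: int | tuple = 60
    n_htd: int = 200
    n_snps: int = 1000
    n_qtl: int = 20
    maf_range: tuple = (0.05, 0.5)
    sigma_s0_sq: float = PROTEIN_SIRE_COMPONENTS[0]
    sigma_s1_sq: float = PROTEIN_SIRE_COMPONENTS[1]
    rho_s: float = PROTEIN_SIRE_COMPONENTS[2]
    sigma_d0_sq: float = 1200.0
    sigma_d1_sq: float = 12.0
    rho_d: float = 0.5
    residual_class_variances: tuple = tuple(np.linspace(900.0, 1800.0, 10))
    mu: float = 1000.0
    b_fixed: float = 40.0
    gxe_mode: str = "additive"
    missing_rate: float = 0.0
    seed: int = 0
    n_grandsires: int | None = None
    qtl_var_fraction: float = 0.3
    qtl_large_fraction: float = 0.1
    qtl_large_ratio: float = 10.0
    records_per_daughter: int = 1

    def __post_init__(self):
        if self.n_sires < 2:
            raise ConfigurationError("n_sires must be >= 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range {self.maf_range} must lie within (0, 0.5]")
        for name in ("sigma_s0_sq", "sigma_s1_sq", "sigma_d0_sq", "sigma_d1_sq"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if abs(self.rho_s) > 1 or abs(self.rho_d) > 1:
            raise ConfigurationError("correlations must lie in [-1, 1]")
        if any(v <= 0 for v in self.residual_class_variances):
            raise ConfigurationError("residual class variances must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.gxe_mode not in ("additive", "multiplicative"):
            raise ConfigurationError(f"unknown gxe_mode {self.gxe_mode!r}")
        if self.n_qtl > self.n_snps:
            raise ConfigurationError("n_qtl cannot exceed n_snps")
        if self.gxe_mode == "additive" and self.n_qtl == 1:
            raise ConfigurationError(
                "additive mode needs n_qtl == 0 or >= 2 to calibrate a correlated "
                "intercept-slope QTL architecture"
            )
        if not 0.0 <= self.qtl_var_fraction < 1.0:
            raise ConfigurationError("qtl_var_fraction must lie in [0, 1)")
        if self.gxe_mode == "multiplicative" and self.mu <= 0:
            raise ConfigurationError("multiplicative mode requires a positive mu")
        if self.records_per_daughter < 1:
            raise ConfigurationError("records_per_daughter must be >= 1")

    @classmethod
    def multiplicative(cls, **overrides) -> "SimulationConfig":
        """Preset for pure-scaling GxE: log-scale model without slopes.

        Variance fields are interpreted on the (dimensionless) log
        scale; ``mu`` stays on the observed scale and becomes the
        geometric-mean yield.  The log-scale residual is homoscedastic.
        """
        defaults = dict(
            gxe_mode="multiplicative",
            mu=1000.0,
            b_fixed=0.1,
            sigma_s0_sq=0.003,
            sigma_s1_sq=0.0,
            rho_s=0.0,
            sigma_d0_sq=0.0015,
            sigma_d1_sq=0.0,
            rho_d=0.0,
            residual_class_variances=(0.0017,) * 10,
            qtl_var_fraction=0.3,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stage]])

    @property
    def grandsire_count(self) -> int:
        return self.n_grandsires if self.n_grandsires is not None else max(2, self.n_sires // 10)

    def sire_covariance(self) -> np.ndarray:
        cov = self.rho_s * np.sqrt(self.sigma_s0_sq * self.sigma_s1_sq)
        return np.array([[self.sigma_s0_sq, cov], [cov, self.sigma_s1_sq]])

    def daughter_covariance(self) -> np.ndarray:
        cov = self.rho_d * np.sqrt(self.sigma_d0_sq * self.sigma_d1_sq)
        return np.array([[self.sigma_d0_sq, cov], [cov, self.sigma_d1_sq]])


@dataclass
class SimulationTruth:
    """Ground truth retained for recovery tests (never an analysis input)."""

    config: SimulationConfig
    sire_effects: pd.DataFrame  # sire_id, s0, s1
    qtl_effects: pd.DataFrame  # snp_index, snp_id, alpha0, alpha1
    environments: pd.Series | None = None  # htd_id -> standardised value
    daughter_effects: pd.DataFrame | None = None  # daughter_id, sire_id, d0, d1


def _sire_ids(n):
    width = max(4, len(str(n)))
    return np.array([f"S{i + 1:0{width}d}" for i in range(n)], dtype=object)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes for the sires at unlinked biallelic SNPs.

    The counted allele (dosage 2) is the '"A"' allele whose frequency is
    drawn as 1 - maf, so dosages count the common allele.  SNPs are
    spread over 29 autosomes with deterministic positions.
    """
    rng = config.rng("genotypes")
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], config.n_snps)
    freq = 1.0 - mafs
    calls = rng.binomial(2, freq[None, :], size=(config.n_sires, config.n_snps)).astype(np.int8)
    if config.missing_rate > 0:
        mask = config.rng("missing").random(calls.shape) < config.missing_rate
        calls[mask] = MISSING
    chrom = (np.arange(config.n_snps) % 29 + 1).astype(str)
    within = np.arange(config.n_snps) // 29
    pos = (within + 1) * 10_000
    snps = pd.DataFrame(
        {
            "snp_id": [f"SNP{k + 1:06d}" for k in range(config.n_snps)],
            "chrom": chrom,
            "pos": pos,
            "allele1": "A",
            "allele2": "B",
            "counted_allele": "A",
        }
    )
    return GenotypeMatrix(_sire_ids(config.n_sires), snps, calls)


def simulate_pedigree(config: SimulationConfig) -> pd.DataFrame:
    """Two-generation sire pedigree: grandsire founders plus the sires.

    Each sire's sire is a uniformly drawn grandsire; dams are unknown.
    Returns a 3-column table (id, sire, dam) with '0' for unknown.
    """
    rng = config.rng("pedigree")
    n_gs = config.grandsire_count
    grandsires = np.array([f"GS{i + 1:04d}" for i in range(n_gs)], dtype=object)
    sires = _sire_ids(config.n_sires)
    assigned = grandsires[rng.integers(0, n_gs, config.n_sires)]
    return pd.DataFrame(
        {
            "id": np.concatenate([grandsires, sires]),
            "sire": np.concatenate([np.full(n_gs, "0", dtype=object), assigned]),
            "dam": np.full(n_gs + config.n_sires, "0", dtype=object),
        }
    )


def simulate_sire_effects(config: SimulationConfig, genotypes: GenotypeMatrix) -> SimulationTruth:
    """True sire intercept/slope effects: QTL part plus polygenic remainder.

    QTL effects are drawn from a two-component mixture (many small, few
    large) and rescaled so the realised QTL covariance over sires equals
    ``qtl_var_fraction`` times the configured sire covariance exactly;
    the polygenic remainder is drawn with the complementary covariance,
    so the total converges to the configured 2x2 matrix.  In
    multiplicative mode effects live on the log scale and the slope
    column is identically zero.
    """
    rng = config.rng("sire_effects")
    q = config.n_sires
    multiplicative = config.gxe_mode == "multiplicative"
    if multiplicative:
        target = np.array([[config.sigma_s0_sq]])
    else:
        target = config.sire_covariance()
    k = target.shape[0]

    qtl_idx = np.array([], dtype=int)
    g_qtl = np.zeros((q, k))
    alphas = np.zeros((0, k))
    if config.n_qtl > 0 and config.qtl_var_fraction > 0:
        qtl_idx = np.sort(rng.choice(config.n_snps, size=config.n_qtl, replace=False))
        x = genotypes.calls[:, qtl_idx].astype(float)
        miss = x < 0
        if miss.any():
            col_mean = np.where(
                (~miss).sum(axis=0) > 0,
                np.where(miss, 0, x).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
                1.0,
            )
            x[miss] = np.broadcast_to(col_mean, x.shape)[miss]
        x = x - x.mean(axis=0)

        large = rng.random(config.n_qtl) < config.qtl_large_fraction
        scale = np.where(large, np.sqrt(config.qtl_large_ratio), 1.0)
        if k == 2:
            rho = config.rho_s
            z = rng.standard_normal((config.n_qtl, 2))
            raw = np.column_stack([z[:, 0], rho * z[:, 0] + np.sqrt(max(0.0, 1 - rho**2)) * z[:, 1]])
        else:
            raw = rng.standard_normal((config.n_qtl, 1))
        raw *= scale[:, None]
        g_raw = x @ raw
        c_hat = np.cov(g_raw, rowvar=False).reshape(k, k)
        q_target = config.qtl_var_fraction * target
        try:
            t = np.linalg.cholesky(q_target) @ np.linalg.inv(np.linalg.cholesky(c_hat))
        except np.linalg.LinAlgError as exc:
            raise SimulationError(
                "QTL genetic values are rank-deficient; increase n_qtl or sire count"
            ) from exc
        alphas = raw @ t.T
        g_qtl = g_raw @ t.T
        poly_cov = target - q_target
    else:
        poly_cov = target

    eigvals, eigvecs = np.linalg.eigh(poly_cov)
    if eigvals.min() < -1e-9 * max(1.0, np.abs(target).max()):
        raise ConfigurationError("requested QTL variance exceeds the total sire covariance")
    poly_cov = (eigvecs * np.clip(eigvals, 0.0, None)) @ eigvecs.T
    poly = rng.multivariate_normal(np.zeros(k), poly_cov, size=q, method="svd")
    effects = g_qtl + poly

    sire_df = pd.DataFrame(
        {
            "sire_id": genotypes.individuals,
            "s0": effects[:, 0],
            "s1": effects[:, 1] if k == 2 else np.zeros(q),
        }
    )
    qtl_df = pd.DataFrame(
        {
            "snp_index": qtl_idx,
            "snp_id": genotypes.snps["snp_id"].to_numpy()[qtl_idx] if qtl_idx.size else [],
            "alpha0": alphas[:, 0] if alphas.size else [],
            "alpha1": alphas[:, 1] if (alphas.size and k == 2) else np.zeros(len(qtl_idx)),
        }
    )
    return SimulationTruth(config=config, sire_effects=sire_df, qtl_effects=qtl_df)


def simulate_daughter_records(config: SimulationConfig, truth: SimulationTruth) -> pd.DataFrame:
    """Daughter records under the configured generative mode.

    Environments are i.i.d. standard normal per herd-test-day; daughters
    are assigned to herd-test-days uniformly at random and carry
    ``records_per_daughter`` records each (default one).  The returned
    table has columns ``daughter_id, sire_id, htd_id, env,
    residual_class, cy, milk_kg, fat_kg, protein_kg``; the three
    component yields are auxiliary milk-recording traits consistent
    with the environment, from which the descriptor stage can re-derive
    the environmental value.  The true environments and daughter
    effects are stored back into ``truth``.
    """
    rng = config.rng("records")
    q = config.n_sires
    if isinstance(config.daughters_per_sire, (tuple, list)):
        lo, hi = config.daughters_per_sire
        n_d = rng.integers(int(lo), int(hi) + 1, size=q)
    else:
        n_d = np.full(q, int(config.daughters_per_sire))
    total_daughters = int(n_d.sum())

    htd_ids = np.array([f"HTD{k + 1:05d}" for k in range(config.n_htd)], dtype=object)
    env_by_htd = rng.standard_normal(config.n_htd)

    sire_ids = truth.sire_effects["sire_id"].to_numpy()
    s0 = truth.sire_effects["s0"].to_numpy()
    s1 = truth.sire_effects["s1"].to_numpy()
    sire_of_daughter = np.repeat(np.arange(q), n_d)
    within = np.concatenate([np.arange(c) for c in n_d]) if total_daughters else np.array([], int)
    daughter_ids = np.array(
        [f"{sire_ids[j]}_D{i + 1:04d}" for j, i in zip(sire_of_daughter, within)], dtype=object
    )

    multiplicative = config.gxe_mode == "multiplicative"
    if multiplicative:
        g_d = np.array([[config.sigma_d0_sq]])
        d_eff = rng.multivariate_normal(np.zeros(1), g_d, size=total_daughters, method="svd")
        d_eff = np.column_stack([d_eff[:, 0], np.zeros(total_daughters)])
    else:
        d_eff = rng.multivariate_normal(
            np.zeros(2), config.daughter_covariance(), size=total_daughters, method="svd"
        )

    rep = config.records_per_daughter
    n_records = total_daughters * rep
    rec_daughter = np.repeat(np.arange(total_daughters), rep)
    htd_index = rng.integers(0, config.n_htd, size=n_records)
    env = env_by_htd[htd_index]
    classes = assign_residual_classes(env, n_classes=len(config.residual_class_variances))

    if multiplicative:
        sigma_e2 = float(np.mean(config.residual_class_variances))
        e = rng.standard_normal(n_records) * np.sqrt(sigma_e2)
        log_y = (
            np.log(config.mu)
            + config.b_fixed * env
            + s0[sire_of_daughter][rec_daughter]
            + d_eff[rec_daughter, 0]
            + e
        )
        cy = np.exp(log_y)
        if not np.all(np.isfinite(cy)) or np.any(cy <= 0):
            raise SimulationError(
                f"multiplicative mode produced nonpositive or non-finite yields under {config!r}"
            )
    else:
        sd_by_class = np.sqrt(np.asarray(config.residual_class_variances))
        e = rng.standard_normal(n_records) * sd_by_class[classes - 1]
        sj = sire_of_daughter[rec_daughter]
        cy = (
            config.mu
            + config.b_fixed * env
            + s0[sj]
            + s1[sj] * env
            + d_eff[rec_daughter, 0]
            + d_eff[rec_daughter, 1] * env
            + e
        )

    # auxiliary component yields (kg) linear in the environment, so the
    # descriptor stage can recover E from herd-test-day means
    milk = np.clip(25.0 + 2.5 * env + rng.standard_normal(n_records) * 1.5, 0.0, None)
    fat = np.clip(1.0 + 0.10 * env + rng.standard_normal(n_records) * 0.08, 0.0, None)
    protein = np.clip(0.85 + 0.08 * env + rng.standard_normal(n_records) * 0.06, 0.0, None)

    records = pd.DataFrame(
        {
            "daughter_id": daughter_ids[rec_daughter],
            "sire_id": sire_ids[sire_of_daughter][rec_daughter],
            "htd_id": htd_ids[htd_index],
            "env": env,
            "residual_class": classes,
            "cy": cy,
            "milk_kg": milk,
            "fat_kg": fat,
            "protein_kg": protein,
        }
    )
    truth.environments = pd.Series(env_by_htd, index=htd_ids, name="env")
    truth.daughter_effects = pd.DataFrame(
        {
            "daughter_id": daughter_ids,
            "sire_id": sire_ids[sire_of_daughter],
            "d0": d_eff[:, 0],
            "d1": d_eff[:, 1],
        }
    )
    return records


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: genotypes, pedigree, truth, records in one call."""
    genotypes = simulate_genotypes(config)
    pedigree = simulate_pedigree(config)
    truth = simulate_sire_effects(config, genotypes)
    records = simulate_daughter_records(config, truth)
    return genotypes, pedigree, truth, records


def write_truth(truth: SimulationTruth, path) -> None:
    """Write ground truth as CSV, clearly marked test-only in the header."""
    with open(path, "w") as fh:
        fh.write("# SYNTHETIC GROUND TRUTH - test-only; never an analysis input\n")
        fh.write(f"# config: {truth.config}\n")
        truth.sire_effects.to_csv(fh, index=False)
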