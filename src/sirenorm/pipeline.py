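"""End-to-end pipeline orchestration with a reproducible manifest.

Stages: simulate -> qc -> descriptor -> fit-rn -> gwas -> validate ->
compare-scales.  Every stage writes its table under the output
directory and is a pure function of (inputs, config, seed); the run
manifest records per-stage input/output hashes, wall time and the full
effective configuration, so an identical config reproduces identical
bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, environment, kinship, qc, scaling, simulate
from . import reaction_norm as rn
from .errors import ConfigurationError
from .genotypes import read_plink, write_plink

logger = logging.getLogger("sirenorm")


@dataclasses.dataclass
class RunConfig:
    """Structured configuration of a full pipeline run."""

    out_dir: str = "sirenorm_run"
    seed: int = 0
    simulation: dict = dataclasses.field(default_factory=dict)
    ped_path: str | None = None  # use existing PLINK input instead of simulating
    map_path: str | None = None
    records_path: str | None = None
    pedigree_path: str | None = None
    trait: str = "cy"
    mode: str = "heterogeneous_slope_daughter"
    use_estimated_descriptor: bool = True
    n_residual_classes: int = 10
    max_missing: float = 0.10
    maf_min: float = 0.03
    call_rate_min: float = 0.90
    hwe_alpha: float = 0.001
    n_validation: int = 500
    discovery_alpha: float = association.DISCOVERY_ALPHA
    validation_alpha: float = association.VALIDATION_ALPHA
    compare_scales: bool = False

    def __post_init__(self):
        for name in ("discovery_alpha", "validation_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name}={v} must lie in (0, 1)")
        for name in ("ped_path", "map_path", "records_path", "pedigree_path"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"{name} {path!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: RunConfig):
        self.stages = []
        self.config = dataclasses.asdict(config)

    def record(self, stage: str, outputs, t0: float):
        self.stages.append(
            {
                "stage": stage,
                "outputs": {p.name: _sha256(p) for p in outputs},
                "wall_time_s": round(time.time() - t0, 3),
            }
        )
        logger.info("[%s] done (%.2fs)", stage, time.time() - t0)

    def write(self, path: Path):
        path.write_text(json.dumps({"config": self.config, "stages": self.stages},
                                   indent=2, default=str) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict.

    Any stage failure raises with the stage name; outputs of completed
    stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    stage = "init"
    try:
        # --- simulate or load -------------------------------------------
        stage = "simulate"
        t0 = time.time()
        if config.records_path is None:
            sim_kwargs = dict(config.simulation)
            sim_kwargs.setdefault("seed", config.seed)
            sim_config = (
                simulate.SimulationConfig.multiplicative(**{k: v for k, v in sim_kwargs.items() if k != "gxe_mode"})
                if sim_kwargs.get("gxe_mode") == "multiplicative"
                else simulate.SimulationConfig(**sim_kwargs)
            )
            genotypes, pedigree, truth, records = simulate.simulate_dataset(sim_config)
            write_plink(genotypes, out / "genotypes.ped", out / "genotypes.map")
            pedigree.to_csv(out / "pedigree.csv", index=False)
            records.to_csv(out / "records.csv", index=False)
            simulate.write_truth(truth, out / "truth_synthetic.csv")
            manifest.record(stage, [out / "genotypes.ped", out / "genotypes.map",
                                    out / "pedigree.csv", out / "records.csv",
                                    out / "truth_synthetic.csv"], t0)
        else:
            genotypes = read_plink(config.ped_path, config.map_path)
            records = pd.read_csv(config.records_path)
            pedigree = pd.read_csv(config.pedigree_path)
            manifest.record("load", [], t0)

        # --- qc ----------------------------------------------------------
        stage = "qc"
        t0 = time.time()
        genotypes, report = qc.run_qc(
            genotypes,
            max_missing=config.max_missing,
            maf_min=config.maf_min,
            call_rate_min=config.call_rate_min,
            hwe_alpha=config.hwe_alpha,
        )
        report.snp_table.to_csv(out / "qc_snps.csv", index=False)
        report.individual_table.to_csv(out / "qc_individuals.csv", index=False)
        manifest.record(stage, [out / "qc_snps.csv", out / "qc_individuals.csv"], t0)

        # drop records of sires removed by QC
        kept = set(map(str, genotypes.individuals))
        records = records[records["sire_id"].astype(str).isin(kept)].reset_index(drop=True)

        # --- descriptor --------------------------------------------------
        stage = "descriptor"
        t0 = time.time()
        descriptor = environment.compute_environment_descriptor(records)
        descriptor.to_csv(out / "descriptor.csv", index=False)
        if config.use_estimated_descriptor:
            records = environment.attach_environment(records, descriptor, config.n_residual_classes)
        manifest.record(stage, [out / "descriptor.csv"], t0)

        # --- reaction norm ----------------------------------------------
        stage = "fit-rn"
        t0 = time.time()
        fit, estimates = rn.fit_reaction_norm(records, mode=config.mode, trait=config.trait)
        (out / "components.json").write_text(json.dumps(fit.components(), indent=2) + "\n")
        estimates.to_csv(out / "sire_estimates.csv", index=False)
        manifest.record(stage, [out / "components.json", out / "sire_estimates.csv"], t0)

        # --- split + gwas + validation ----------------------------------
        stage = "gwas"
        t0 = time.time()
        split = association.split_sires(
            estimates["sire_id"].tolist(), n_validation=config.n_validation, seed=config.seed
        )
        a_matrix = kinship.build_numerator_relationship(pedigree, estimates["sire_id"].tolist())
        disc = estimates[estimates["sire_id"].isin(split.discovery)]
        valid = estimates[estimates["sire_id"].isin(split.validation)]
        tables = {}
        for component in ("gp", "es"):
            tables[component] = association.run_gwas(
                disc, genotypes, a_matrix, component=component, alpha=config.discovery_alpha
            )
            tables[component].to_csv(out / f"gwas_{component}.csv", index=False)
        manifest.record(stage, [out / "gwas_gp.csv", out / "gwas_es.csv"], t0)

        stage = "validate"
        t0 = time.time()
        for component in ("gp", "es"):
            confirmed = association.validate_snps(
                tables[component], valid, genotypes, a_matrix,
                component=component, alpha=config.validation_alpha,
            )
            confirmed.to_csv(out / f"validation_{component}.csv", index=False)
        manifest.record(stage, [out / "validation_gp.csv", out / "validation_es.csv"], t0)

        # --- scale comparison (optional) --------------------------------
        if config.compare_scales:
            stage = "compare-scales"
            t0 = time.time()
            comparison = scaling.run_scale_comparison(
                records, genotypes, a_matrix, split, trait=config.trait,
                discovery_alpha=config.discovery_alpha,
                validation_alpha=config.validation_alpha,
            )
            comparison.table.to_csv(out / "scale_comparison.csv", index=False)
            manifest.record(stage, [out / "scale_comparison.csv"], t0)
    except Exception as exc:
        manifest.write(out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.write(out / "manifest.json")
    return json.loads((out / "manifest.json").read_text())
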