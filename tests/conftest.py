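import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import sirenorm as sn


@pytest.fixture(scope="session")
def small_dataset():
    """A small additive-mode dataset shared by read-only tests."""
    config = sn.SimulationConfig(
        n_sires=30, daughters_per_sire=12, n_htd=50, n_snps=60, n_qtl=6,
        missing_rate=0.02, seed=1234,
    )
    genotypes, pedigree, truth, records = sn.simulate_dataset(config)
    return {
        "config": config,
        "genotypes": genotypes,
        "pedigree": pedigree,
        "truth": truth,
        "records": records,
    }


def make_records(n_sires=4, n_daughters=4, seed=0, n_classes=3, records_per_daughter=1,
                 **config_overrides):
    """Tiny synthetic record tables for oracle-equivalence tests."""
    kwargs = dict(
        n_sires=n_sires,
        daughters_per_sire=n_daughters,
        n_htd=max(8, n_daughters * 2),
        n_snps=10,
        n_qtl=0,
        residual_class_variances=tuple(np.linspace(800.0, 1600.0, n_classes)),
        records_per_daughter=records_per_daughter,
        seed=seed,
    )
    kwargs.update(config_overrides)
    config = sn.SimulationConfig(**kwargs)
    _, pedigree, truth, records = sn.simulate_dataset(config)
    return records, pedigree, truth, config
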