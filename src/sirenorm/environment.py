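"""Continuous environmental descriptor for herd-test-day environments.

The environment of a herd test day (HTD, a herd-by-recording-date
stratum) is described by its mean milk *energy yield*, a single linear
combination of milk, fat and protein yield that summarises the three
highly correlated production levels.  Descriptors are standardised over
herd-test-days to mean 0 and SD 1 (sample SD, each HTD weighted
equally), so positive values are superior environments and 0 is the
average environment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateDataError

#: energy-yield weights for (milk, fat, protein), yields in kilograms
ENERGY_COEFFICIENTS = (0.802, 38.4, 23.6)


def compute_energy_yield(milk_kg, fat_kg, protein_kg):
    """Milk energy yield ``0.802*milk + 38.4*fat + 23.6*protein`` (kg inputs).

    Accepts scalars or arrays; negative inputs raise ``ValueError``.
    """
    milk = np.asarray(milk_kg, dtype=float)
    fat = np.asarray(fat_kg, dtype=float)
    protein = np.asarray(protein_kg, dtype=float)
    if np.any(milk < 0) or np.any(fat < 0) or np.any(protein < 0):
        raise ValueError("yields must be non-negative")
    w_milk, w_fat, w_protein = ENERGY_COEFFICIENTS
    out = w_milk * milk + w_fat * fat + w_protein * protein
    return out if out.ndim else float(out)


def compute_environment_descriptor(records: pd.DataFrame) -> pd.DataFrame:
    """Per-HTD energy-yield level, raw and standardised.

    Parameters
    ----------
    records : DataFrame
        Must carry ``htd_id, milk_kg, fat_kg, protein_kg``; every HTD id
        appearing in the table has at least one record by construction.

    Returns
    -------
    DataFrame with columns ``htd_id, raw, standardized``; standardised
    values have mean 0 and sample SD 1 over herd-test-days.
    """
    required = {"htd_id", "milk_kg", "fat_kg", "protein_kg"}
    missing = required - set(records.columns)
    if missing:
        raise KeyError(f"records table lacks columns {sorted(missing)}")
    energy = compute_energy_yield(
        records["milk_kg"].to_numpy(), records["fat_kg"].to_numpy(), records["protein_kg"].to_numpy()
    )
    raw = pd.Series(energy, index=records["htd_id"].to_numpy()).groupby(level=0).mean()
    sd = raw.std(ddof=1)
    if len(raw) < 2 or not np.isfinite(sd) or sd == 0:
        raise DegenerateDataError(
            "herd-test-day energy-yield levels have zero spread; descriptor undefined"
        )
    standardized = (raw - raw.mean()) / sd
    return pd.DataFrame(
        {"htd_id": raw.index.to_numpy(), "raw": raw.to_numpy(), "standardized": standardized.to_numpy()}
    )


def assign_residual_classes(env_values, n_classes: int = 10) -> np.ndarray:
    """Split records into ``n_classes`` contiguous environment classes.

    Records are ranked by environment value (stable sort, so ties keep
    record order); class sizes differ by at most one, with remainder
    records placed in the lowest classes.  Returns 1-based class labels
    aligned with the input order.
    """
    env = np.asarray(env_values, dtype=float)
    n = env.size
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if n < n_classes:
        raise ValueError(f"cannot form {n_classes} classes from {n} records")
    order = np.argsort(env, kind="stable")
    base, rem = divmod(n, n_classes)
    sizes = np.full(n_classes, base, dtype=int)
    sizes[:rem] += 1
    labels_sorted = np.repeat(np.arange(1, n_classes + 1), sizes)
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def attach_environment(records: pd.DataFrame, descriptor: pd.DataFrame, n_classes: int = 10) -> pd.DataFrame:
    """Merge standardised HTD descriptors onto records and label residual classes.

    Adds/overwrites columns ``env`` (standardised descriptor of the
    record's HTD) and ``residual_class``.
    """
    env_map = descriptor.set_index("htd_id")["standardized"]
    missing = set(records["htd_id"]) - set(env_map.index)
    if missing:
        raise KeyError(f"no descriptor for herd-test-days {sorted(missing)[:5]}")
    out = records.copy()
    out["env"] = env_map.reindex(out["htd_id"]).to_numpy()
    out["residual_class"] = assign_residual_classes(out["env"].to_numpy(), n_classes)
    return out
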