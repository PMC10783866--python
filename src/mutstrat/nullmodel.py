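"""Randomized-mutation null model: patient bootstrap followed by
within-patient permutation.

The null destroys genotype-phenotype linkage while preserving each
patient's mutation burden: patients are resampled with replacement
(survival records travel with their mutation rows), then every row's ones
are reassigned to genes drawn uniformly without replacement across the
panel.  Row sums are preserved exactly; gene (column) frequencies are
destroyed.  Run through the full pipeline this matrix should yield no
subtype survival signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["RandomizedProfile", "bootstrap_patients", "permute_within_patients"]


@dataclass
class RandomizedProfile:
    mutations: pd.DataFrame
    seed: int
    bootstrap_indices: np.ndarray | None = None


def bootstrap_patients(
    profile: pd.DataFrame, records: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Sample n patients with replacement; mutation rows and survival
    records are drawn jointly and resampled ids disambiguated by suffix."""
    n = len(profile)
    if n < 2:
        raise DataError("bootstrap needs at least 2 samples")
    if not profile.index.equals(records.loc[profile.index].index):
        raise DataError("profile and records must share sample ids")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=n)
    new_ids = [f"{profile.index[i]}_b{j}" for j, i in enumerate(idx)]
    boot_profile = profile.iloc[idx].set_axis(pd.Index(new_ids, name="sample_id"))
    boot_records = records.loc[profile.index].iloc[idx].set_axis(
        pd.Index(new_ids, name="sample_id")
    )
    return boot_profile, boot_records, idx


def permute_within_patients(profile: pd.DataFrame, seed: int) -> RandomizedProfile:
    """Reassign each row's m mutations to m genes drawn uniformly without
    replacement across the whole panel; row sums preserved exactly."""
    values = profile.to_numpy()
    if not ((values == 0) | (values == 1)).all():
        raise DataError("profile must be binary")
    rng = np.random.default_rng(seed)
    n, G = values.shape
    out = np.zeros_like(values)
    row_sums = values.sum(axis=1)
    for i in range(n):
        m = int(row_sums[i])
        if m:
            out[i, rng.choice(G, size=m, replace=False)] = 1
    mutations = pd.DataFrame(out, index=profile.index, columns=profile.columns)
    return RandomizedProfile(mutations=mutations, seed=seed)
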