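"""Cohort hygiene, the random-normal-sort train/test split, and the
poor-prognosis-first cluster label convention."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .sdcn import ClusterAssignment
from .survival import km_median

logger = logging.getLogger(__name__)

__all__ = ["CohortSplit", "filter_cohort", "split_cohort", "orient_cluster_labels"]


@dataclass(frozen=True)
class CohortSplit:
    training: tuple[str, ...]
    testing: tuple[str, ...]
    seed: int
    method: str = "standard-normal descending sort, top n_train"


def filter_cohort(
    mutations: pd.DataFrame, records: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop samples lacking survival time or event status and align the
    mutation matrix to the surviving clinical records (strict inner join)."""
    complete = records.dropna(subset=["os_months", "os_event"])
    n_missing = len(records) - len(complete)
    common = mutations.index.intersection(complete.index)
    n_unmatched = len(mutations) - len(common)
    if n_missing:
        logger.info("excluded %d samples with missing survival data", n_missing)
    if n_unmatched:
        logger.warning("dropped %d mutation rows without clinical records", n_unmatched)
    if len(common) == 0:
        raise DataError("no samples left after filtering")
    return mutations.loc[common], complete.loc[common]


def split_cohort(records: pd.DataFrame, n_train: int, seed: int) -> CohortSplit:
    """Partition samples by drawing one standard-normal number each,
    sorting descending and taking the top ``n_train`` as training."""
    n = len(records)
    if not 0 < n_train < n:
        raise ParameterError(f"n_train must be in (0, {n}), got {n_train}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    order = np.argsort(-z, kind="stable")
    ids = records.index.to_numpy()
    training = ids[order[:n_train]]
    testing = ids[order[n_train:]]
    return CohortSplit(training=tuple(training), testing=tuple(testing), seed=seed)


def orient_cluster_labels(
    assignment: ClusterAssignment, records: pd.DataFrame
) -> ClusterAssignment:
    """For k=2, relabel so cluster 1 has the worse (smaller) Kaplan-Meier
    median survival; ties go to the larger cluster.  Idempotent; k != 2
    assignments are returned unchanged with a note."""
    if assignment.k != 2:
        logger.info("orientation skipped: k=%d != 2", assignment.k)
        return assignment
    labels = assignment.labels
    rec = records.loc[labels.index]
    medians = {}
    sizes = {}
    for c in (1, 2):
        sub = rec[labels == c]
        if sub.empty:
            raise DataError(f"cluster {c} is empty")
        medians[c] = km_median(sub)
        sizes[c] = len(sub)
    if medians[1] == medians[2]:
        worse = 1 if sizes[1] >= sizes[2] else 2
    else:
        worse = min(medians, key=lambda c: medians[c])
    if worse == 1:
        return assignment
    flipped = labels.map({1: 2, 2: 1})
    return ClusterAssignment(
        labels=flipped,
        silhouette=assignment.silhouette,
        average_silhouette=assignment.average_silhouette,
        k=2,
        losses=assignment.losses,
    )
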