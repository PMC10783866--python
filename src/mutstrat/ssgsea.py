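"""Single-sample gene-set enrichment scoring of smoothed mutation profiles.

Each sample's smoothed profile is scored against each gene set with the
single-sample GSEA statistic: genes are ranked by value in descending
order, and a running sum accrues, at each position, the in-set rank weight
(|rank|^alpha, normalized by the set's total weight; the top-ranked gene
carries rank N) minus the uniform out-of-set decrement 1/(N - |set|).  The
enrichment score is the integral (sum over positions) of that running
difference, so a set concentrated at the top of the ranking scores high.
With ``normalize=True`` every score in the matrix is divided by the global
(max - min), the normalization the ssGSEA variant of GSVA applies per
cohort.

Scoring every gene as its own singleton set yields the "gene-level
profile", a rank-monotone surrogate for an expression matrix when only
mutation data exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "PathwayActivityMatrix",
    "rank_transform",
    "ssgsea_sample",
    "activity_matrix",
    "gene_level_profile",
]

DEFAULT_ALPHA = 0.25


@dataclass
class GeneSetCollection:
    """Named, nonempty gene sets with unique names."""

    sets: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self):
        if not self.sets:
            raise DataError("gene-set collection is empty")
        for name, genes in self.sets.items():
            if not genes:
                raise DataError(f"gene set {name!r} is empty")
        self.sets = {name: list(genes) for name, genes in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class PathwayActivityMatrix:
    scores: pd.DataFrame  # samples x sets
    normalized: bool
    alpha: float


def rank_transform(values: np.ndarray, tie_rule: str = "stable") -> np.ndarray:
    """Dense descending ranks: the largest value gets rank 1.

    Ties resolve by ``tie_rule``: "stable" keeps input order (the package
    stores matrices with gene-id-sorted columns, so stable order is
    gene-id order).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DataError("cannot rank an empty vector")
    if np.isnan(values).any():
        raise DataError("NaN in values passed to rank_transform")
    if tie_rule != "stable":
        raise ParameterError(f"unknown tie_rule {tie_rule!r}")
    order = np.argsort(-values, kind="stable")
    ranks = np.empty(values.size, dtype=int)
    ranks[order] = np.arange(1, values.size + 1)
    return ranks


def _es_from_order(
    in_set_ordered: np.ndarray, alpha: float
) -> np.ndarray:
    """Integrated running-sum ES for rows of an (n_samples, N) boolean array
    whose columns already follow each sample's descending-value order."""
    n, N = in_set_ordered.shape
    m = in_set_ordered.sum(axis=1)
    # rank weight at position pos (0-based) is (N - pos)^alpha: top gene
    # carries the largest rank weight
    w = (N - np.arange(N)).astype(float) ** alpha
    win = in_set_ordered * w
    step_in = win / win.sum(axis=1, keepdims=True)
    step_out = (~in_set_ordered) / (N - m)[:, None]
    running = np.cumsum(step_in - step_out, axis=1)
    return running.sum(axis=1)


def ssgsea_sample(
    values: pd.Series | np.ndarray,
    gene_set: list[str] | np.ndarray,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Enrichment score of one sample's gene scores against one gene set.

    ``values`` must be indexed by gene id (a Series) or be paired with a
    boolean membership mask of the same length.
    """
    if isinstance(values, pd.Series):
        genes = values.index.astype(str)
        mask = np.asarray(genes.isin([str(g) for g in gene_set]))
        x = values.to_numpy(dtype=float)
    else:
        x = np.asarray(values, dtype=float)
        mask = np.asarray(gene_set, dtype=bool)
        if mask.shape != x.shape:
            raise ParameterError("array input requires a boolean mask of equal length")
    N = x.size
    if N < 2:
        raise DataError("need at least 2 genes to score")
    m = int(mask.sum())
    if m == 0:
        raise DataError("gene set has empty intersection with the profile")
    if m == N:
        raise DataError("gene set covers every profile gene; out-of-set step undefined")
    order = np.argsort(-x, kind="stable")
    return float(_es_from_order(mask[order][None, :], alpha)[0])


def activity_matrix(
    profile: pd.DataFrame,
    collection: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
) -> PathwayActivityMatrix:
    """Score every (sample, gene set) pair; optionally cohort-normalize.

    Sets with no gene in the profile are dropped with a warning.  The
    normalization divisor (global max - min of the raw score matrix) is
    computed on this cohort's matrix alone.
    """
    if profile.empty:
        raise DataError("empty profile")
    X = profile.to_numpy(dtype=float)
    genes = profile.columns.astype(str)
    N = X.shape[1]
    order = np.argsort(-X, axis=1, kind="stable")

    cols: dict[str, np.ndarray] = {}
    dropped = []
    for name, gene_list in collection.sets.items():
        mask = np.asarray(genes.isin([str(g) for g in gene_list]))
        m = int(mask.sum())
        if m == 0:
            dropped.append(name)
            continue
        if m == N:
            raise DataError(f"gene set {name!r} covers every profile gene")
        cols[name] = _es_from_order(mask[order], alpha)
    if dropped:
        logger.warning("dropped %d gene sets with empty intersection", len(dropped))
    if not cols:
        raise DataError("every gene set had empty intersection with the profile")

    scores = pd.DataFrame(cols, index=profile.index)
    if normalize:
        span = float(scores.to_numpy().max() - scores.to_numpy().min())
        if span > 0:
            scores = scores / span
    return PathwayActivityMatrix(scores=scores, normalized=normalize, alpha=alpha)


def gene_level_profile(
    profile: pd.DataFrame, normalize: bool = True, alpha: float = DEFAULT_ALPHA
) -> PathwayActivityMatrix:
    """Singleton-set ssGSEA: every profile gene is its own gene set.

    For a singleton set the in-set increment is 1 regardless of alpha, so
    the score depends only on the gene's rank position: with the gene at
    (1-based) position k among N,

        ES(k) = (N - k + 1) - [N(N+1)/2 - (N - k + 1)] / (N - 1),

    strictly decreasing in k.  Per sample the scores are therefore a
    monotone transform of the smoothed values (Spearman rho = 1).
    """
    if profile.shape[1] < 3:
        raise DataError("gene-level profile needs at least 3 genes")
    X = profile.to_numpy(dtype=float)
    n, N = X.shape
    order = np.argsort(-X, axis=1, kind="stable")
    pos = np.empty_like(order)
    rows = np.arange(n)[:, None]
    pos[rows, order] = np.arange(1, N + 1)[None, :]
    tail = N - pos + 1.0
    es = tail - (N * (N + 1) / 2.0 - tail) / (N - 1.0)
    scores = pd.DataFrame(es, index=profile.index, columns=profile.columns)
    if normalize:
        span = float(scores.to_numpy().max() - scores.to_numpy().min())
        if span > 0:
            scores = scores / span
    return PathwayActivityMatrix(scores=scores, normalized=normalize, alpha=alpha)
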