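"""Interaction-network loading and random-walk-with-restart smoothing.

A binary somatic mutation profile is sparse: a tumor typically carries a
handful of mutated genes out of hundreds on the panel.  Network propagation
turns each sample's 0/1 vector into a continuous "mutation influence"
distribution by diffusing the mutated-gene mass over a protein-protein
interaction network with a random walk with restart (RWR):

    p_{t+1} = (1 - r) * W @ p_t + r * p_0

where W is the column-normalized weighted adjacency matrix, p_0 the seed
distribution (uniform over the sample's network-mapped mutated genes) and
r the restart probability (default 0.75).  Iteration stops when the
max-norm change between successive iterates drops below ``tol`` (default
1e-6); the fixed point is the stationary distribution
r * (I - (1-r) W)^-1 @ p_0, which tests use as an independent oracle.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConvergenceError, DataError, ParameterError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "RWRParams",
    "TransitionMatrix",
    "SmoothedProfile",
    "load_network",
    "build_transition_matrix",
    "rwr",
    "smooth_profile",
]

DEFAULT_SCORE_THRESHOLD = 700.0


@dataclass(frozen=True)
class GeneNetwork:
    """Filtered, undirected, weighted gene-interaction graph.

    ``genes`` fixes the node order used by every downstream matrix;
    ``adjacency`` is the symmetric weighted adjacency in that order.
    """

    genes: tuple[str, ...]
    adjacency: sp.csr_matrix
    score_threshold: float = DEFAULT_SCORE_THRESHOLD

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def edge_list(self) -> pd.DataFrame:
        """Upper-triangle edge list (gene1, gene2, score), deterministic order."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        order = np.lexsort((coo.col, coo.row))
        return pd.DataFrame(
            {
                "gene1": [self.genes[i] for i in coo.row[order]],
                "gene2": [self.genes[j] for j in coo.col[order]],
                "score": coo.data[order],
            }
        )


@dataclass(frozen=True)
class RWRParams:
    r: float = 0.75
    tol: float = 1e-6
    max_iter: int = 10_000

    def __post_init__(self):
        if not 0.0 < self.r <= 1.0:
            raise ParameterError(f"restart probability r must be in (0, 1], got {self.r}")
        if self.tol <= 0:
            raise ParameterError("tol must be positive")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic walk operator aligned to a gene order."""

    W: sp.csr_matrix
    genes: tuple[str, ...]

    def __post_init__(self):
        colsums = np.asarray(self.W.sum(axis=0)).ravel()
        if not np.allclose(colsums, 1.0, atol=1e-12):
            raise DataError("transition matrix columns must sum to 1")


@dataclass
class SmoothedProfile:
    """Per-sample stationary RWR distributions over the network genes."""

    values: pd.DataFrame  # samples x genes, rows sum to 1
    iterations: int = 0
    unmapped_counts: pd.Series | None = None
    params: RWRParams = field(default_factory=RWRParams)


def _normalize_gene(g: str) -> str:
    return str(g).strip().upper()


def load_network(
    edges: str | os.PathLike | pd.DataFrame,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> GeneNetwork:
    """Build the filtered interaction graph from a 3-column edge list.

    Edges with score <= ``score_threshold`` are dropped; reciprocal and
    duplicate rows collapse to one undirected edge keeping the maximum
    score; self-loops are discarded; genes left without any surviving edge
    do not appear in the node set.
    """
    if isinstance(edges, pd.DataFrame):
        df = edges.iloc[:, :3].copy()
    else:
        df = pd.read_csv(edges, sep=r"\s+", comment="#")
        if df.shape[1] < 3:
            raise ParseError(f"edge list {edges} needs >= 3 columns")
        # headerless files get their first row promoted to header by pandas;
        # detect by a non-numeric score and restore it
        df = df.iloc[:, :3]
        if not str(df.columns[2]).replace(".", "").lstrip("-").isdigit():
            pass  # named header such as combined_score
        else:
            first = pd.DataFrame([df.columns.tolist()])
            df = pd.concat([first.set_axis(df.columns, axis=1), df], ignore_index=True)
    df.columns = ["gene1", "gene2", "score"]
    try:
        df["score"] = pd.to_numeric(df["score"])
    except (ValueError, TypeError) as exc:
        raise ParseError(f"non-numeric interaction score: {exc}") from exc
    if df[["gene1", "gene2"]].isna().any().any() or df["score"].isna().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2
        raise ParseError("malformed edge row", bad)

    df["gene1"] = df["gene1"].map(_normalize_gene)
    df["gene2"] = df["gene2"].map(_normalize_gene)
    n_in = len(df)
    df = df[df["score"] > score_threshold]
    df = df[df["gene1"] != df["gene2"]]
    if df.empty:
        raise DataError(f"no edges left after filtering at score > {score_threshold}")

    # canonical orientation, then collapse duplicates/reciprocals keeping max
    a = df[["gene1", "gene2"]].min(axis=1)
    b = df[["gene1", "gene2"]].max(axis=1)
    collapsed = (
        pd.DataFrame({"gene1": a, "gene2": b, "score": df["score"].to_numpy()})
        .groupby(["gene1", "gene2"], sort=True)["score"]
        .max()
        .reset_index()
    )

    genes = tuple(sorted(set(collapsed["gene1"]) | set(collapsed["gene2"])))
    index = {g: i for i, g in enumerate(genes)}
    i = collapsed["gene1"].map(index).to_numpy()
    j = collapsed["gene2"].map(index).to_numpy()
    w = collapsed["score"].to_numpy(dtype=float)
    n = len(genes)
    adj = sp.coo_matrix(
        (np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n)
    ).tocsr()
    logger.info(
        "network: %d edges in, %d retained (score > %g), %d genes",
        n_in, len(collapsed), score_threshold, n,
    )
    return GeneNetwork(genes=genes, adjacency=adj, score_threshold=score_threshold)


def build_transition_matrix(
    network: GeneNetwork, binarize_edges: bool = False
) -> TransitionMatrix:
    """Column-normalize the (optionally binarized) adjacency: W[:, j] = A[:, j]/deg(j)."""
    if network.n_genes == 0:
        raise DataError("empty network")
    adj = network.adjacency.astype(float)
    if binarize_edges:
        adj = adj.sign()
    colsum = np.asarray(adj.sum(axis=0)).ravel()
    if (colsum == 0).any():
        raise DataError("zero-degree node in network; isolated nodes must be dropped")
    W = (adj @ sp.diags(1.0 / colsum)).tocsr()
    return TransitionMatrix(W=W, genes=network.genes)


def _rwr_matrix(
    P0: np.ndarray, W: sp.csr_matrix, params: RWRParams
) -> tuple[np.ndarray, int]:
    """Iterate P <- (1-r) W P + r P0 on a genes x k seed block until the
    max-norm change over all entries is < tol."""
    r = params.r
    if r == 1.0:
        return P0.copy(), 0
    P = P0.copy()
    for it in range(1, params.max_iter + 1):
        P_next = (1.0 - r) * (W @ P) + r * P0
        delta = float(np.max(np.abs(P_next - P)))
        P = P_next
        if delta < params.tol:
            return P, it
    raise ConvergenceError(
        f"RWR did not converge in {params.max_iter} iterations", residual=delta
    )


def rwr(
    p0: np.ndarray, W: TransitionMatrix | sp.spmatrix, params: RWRParams | None = None
) -> tuple[np.ndarray, int]:
    """Smooth one seed distribution; returns (stationary vector, iterations)."""
    params = params or RWRParams()
    mat = W.W if isinstance(W, TransitionMatrix) else sp.csr_matrix(W)
    p0 = np.asarray(p0, dtype=float).ravel()
    if p0.shape[0] != mat.shape[0]:
        raise ParameterError("seed vector length does not match transition matrix")
    if (p0 < 0).any() or abs(p0.sum() - 1.0) > 1e-9:
        raise ParameterError("seed vector must be nonnegative and sum to 1")
    P, iters = _rwr_matrix(p0[:, None], mat, params)
    return P.ravel(), iters


def smooth_profile(
    mutations: pd.DataFrame,
    network: GeneNetwork,
    params: RWRParams | None = None,
    binarize_edges: bool = False,
    on_unmapped_sample: str = "error",
) -> SmoothedProfile:
    """Smooth every sample's binary mutation vector over the network.

    The seed for a sample places uniform mass 1/m on its m mutated genes
    that map (case-insensitive exact match) to network nodes; all other
    genes start at zero.  Samples whose mutations all fall outside the
    network either raise (default) or are excluded with a warning
    (``on_unmapped_sample="exclude"``).
    """
    if mutations.empty:
        raise DataError("mutation matrix has no samples")
    if on_unmapped_sample not in ("error", "exclude"):
        raise ParameterError("on_unmapped_sample must be 'error' or 'exclude'")
    params = params or RWRParams()
    tm = build_transition_matrix(network, binarize_edges=binarize_edges)

    index = {_normalize_gene(g): i for i, g in enumerate(network.genes)}
    cols = [_normalize_gene(c) for c in mutations.columns]
    mapped = np.array([index.get(c, -1) for c in cols])
    in_net = mapped >= 0

    M = mutations.to_numpy(dtype=float)
    n_samples, _ = M.shape
    n_genes = network.n_genes
    P0 = np.zeros((n_genes, n_samples))
    unmapped = np.zeros(n_samples, dtype=int)
    dropped: list[int] = []
    for s in range(n_samples):
        row = M[s] > 0
        hits = mapped[row & in_net]
        unmapped[s] = int(row.sum() - hits.size)
        if hits.size == 0:
            if on_unmapped_sample == "error":
                raise DataError(
                    f"sample {mutations.index[s]!r} has no network-mapped mutations"
                )
            dropped.append(s)
            continue
        P0[hits, s] = 1.0 / hits.size
    keep = [s for s in range(n_samples) if s not in set(dropped)]
    if not keep:
        raise DataError("no samples left after dropping unmapped samples")
    if dropped:
        logger.warning("excluded %d samples with zero network-mapped mutations", len(dropped))
    if unmapped.sum():
        logger.warning(
            "dropped %d mutated-gene hits absent from the network across %d samples",
            int(unmapped.sum()), int((unmapped > 0).sum()),
        )

    P, iters = _rwr_matrix(P0[:, keep], tm.W, params)
    values = pd.DataFrame(
        P.T, index=mutations.index[keep], columns=list(network.genes)
    )
    return SmoothedProfile(
        values=values,
        iterations=iters,
        unmapped_counts=pd.Series(unmapped[keep], index=mutations.index[keep]),
        params=params,
    )
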