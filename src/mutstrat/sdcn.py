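"""Structural deep clustering of samples on pathway-activity features.

The clustering couples two branches over the same samples:

* an autoencoder (AE) that learns a low-dimensional embedding h_i of each
  sample's pathway-activity vector, trained for reconstruction;
* a graph convolutional network (GCN) over a KNN sample-similarity graph,
  whose layer l input mixes its own representation with the AE's layer-l
  activation, (1 - eps) * Z_l + eps * H_l, so semantic information is
  delivered layer by layer; its final layer is a softmax over clusters.

Self-supervision: soft assignments q_ij come from a Student's-t kernel
(one degree of freedom) between h_i and learnable cluster centers mu_j
(initialized by k-means on the pretrained embedding); a sharpened target
distribution p_ij ∝ q_ij^2 / sum_i q_ij supervises both branches through
KL(P || Q) and KL(P || Z).  The total loss is

    L = w_rec * ||X - X_hat||^2 / (n d)  +  w_clu * KL(P||Q)/n  +  w_gcn * KL(P||Z)/n

optimized full-batch with Adam; everything is plain NumPy with manual
backpropagation (gradients are verified against finite differences in the
test suite).  Hard labels come from the GCN branch by default.  The number
of clusters is selected by the average silhouette width over a k range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors

from .errors import DataError, ParameterError, TrainingError

logger = logging.getLogger(__name__)

__all__ = [
    "SampleGraph",
    "SDCNConfig",
    "ClusterAssignment",
    "standardize_features",
    "build_knn_graph",
    "pretrain_autoencoder",
    "train_sdcn",
    "average_silhouette",
    "select_n_clusters",
]


@dataclass
class SampleGraph:
    """Binary symmetric KNN adjacency over samples (zero diagonal)."""

    adjacency: sp.csr_matrix
    k_neighbors: int
    metric: str = "euclidean"


@dataclass(frozen=True)
class SDCNConfig:
    """Hyperparameters; defaults follow the original SDCN recipe
    (encoder 500-500-2000, embedding 10, loss weights 1/0.1/0.01, 10
    neighbors) and are all overridable."""

    encoder_dims: tuple[int, ...] = (500, 500, 2000)
    embedding_dim: int = 10
    n_clusters: int = 2
    pretrain_epochs: int = 200
    train_epochs: int = 200
    learning_rate: float = 1e-3
    loss_weights: tuple[float, float, float] = (1.0, 0.1, 0.01)
    k_neighbors: int = 10
    epsilon: float = 0.5
    gcn_lr_multiplier: float = 10.0  # the softly-weighted GCN head needs larger steps
    head: str = "gcn"  # which branch yields hard labels: "gcn" or "ae"
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ParameterError("n_clusters must be >= 1")
        if any(d <= 0 for d in (*self.encoder_dims, self.embedding_dim)):
            raise ParameterError("layer widths must be positive")
        if self.head not in ("gcn", "ae"):
            raise ParameterError("head must be 'gcn' or 'ae'")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ParameterError("epsilon must be in [0, 1]")


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample id -> label in 1..k
    silhouette: pd.Series | None
    average_silhouette: float | None
    k: int
    losses: list[float] = field(default_factory=list)


def standardize_features(features: pd.DataFrame) -> pd.DataFrame:
    """Zero-mean, unit-variance per feature; constant features stay zero."""
    X = features.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return pd.DataFrame((X - mu) / sd, index=features.index, columns=features.columns)


def build_knn_graph(
    features: pd.DataFrame | np.ndarray, k_neighbors: int, metric: str = "euclidean"
) -> SampleGraph:
    """Union-symmetrized k-nearest-neighbor graph over samples."""
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    n = X.shape[0]
    if not 1 <= k_neighbors < n:
        raise ParameterError(f"need n_samples > k_neighbors >= 1, got n={n}, k={k_neighbors}")
    if pd.DataFrame(X).duplicated().any():
        logger.warning("duplicate samples present; neighbor ties resolved by index order")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1, metric=metric).fit(X)
    _, idx = nn.kneighbors(X)
    rows, cols = [], []
    for i in range(n):
        neigh = [j for j in idx[i] if j != i][:k_neighbors]
        rows.extend([i] * len(neigh))
        cols.extend(neigh)
    A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    A = A.maximum(A.T)  # union symmetrization
    A.setdiag(0)
    A.eliminate_zeros()
    A.data[:] = 1.0
    return SampleGraph(adjacency=A.tocsr(), k_neighbors=k_neighbors, metric=metric)


# ---------------------------------------------------------------------------
# low-level neural-network machinery (full-batch, NumPy)


def _relu(z):
    return np.maximum(z, 0.0)


def _init_linear(rng, fan_in, fan_out):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)), np.zeros(fan_out)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, lrs: list[float] | None = None):
        self.params = params
        self.lrs = lrs if lrs is not None else [lr] * len(params)
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for p, g, m, v, lr in zip(self.params, grads, self.m, self.v, self.lrs):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


class _Autoencoder:
    """MLP autoencoder: ReLU hidden layers, linear embedding and output."""

    def __init__(self, d_in: int, hidden: tuple[int, ...], d_emb: int, rng):
        enc_dims = [d_in, *hidden, d_emb]
        dec_dims = [d_emb, *reversed(hidden), d_in]
        self.enc = [_init_linear(rng, a, b) for a, b in zip(enc_dims, enc_dims[1:])]
        self.dec = [_init_linear(rng, a, b) for a, b in zip(dec_dims, dec_dims[1:])]

    def params(self) -> list[np.ndarray]:
        return [a for W, b in (*self.enc, *self.dec) for a in (W, b)]

    def forward(self, X):
        """Returns (hidden activations H1..HL, embedding h, reconstruction,
        caches for backward)."""
        acts, pre = [X], []
        a = X
        for i, (W, b) in enumerate(self.enc):
            z = a @ W + b
            pre.append(z)
            a = z if i == len(self.enc) - 1 else _relu(z)
            acts.append(a)
        h = a
        d_acts, d_pre = [h], []
        for i, (W, b) in enumerate(self.dec):
            z = d_acts[-1] @ W + b
            d_pre.append(z)
            d_acts.append(z if i == len(self.dec) - 1 else _relu(z))
        X_hat = d_acts[-1]
        return acts[1:-1], h, X_hat, (acts, pre, d_acts, d_pre)

    def backward(self, caches, dX_hat, dh_extra, dH_extra):
        """Backprop given upstream grads on the reconstruction, on the
        embedding, and on each encoder hidden activation (GCN injection)."""
        acts, pre, d_acts, d_pre = caches
        g_enc = [[np.zeros_like(W), np.zeros_like(b)] for W, b in self.enc]
        g_dec = [[np.zeros_like(W), np.zeros_like(b)] for W, b in self.dec]
        # decoder
        delta = dX_hat
        for i in reversed(range(len(self.dec))):
            if i != len(self.dec) - 1:
                delta = delta * (d_pre[i] > 0)
            g_dec[i][0] = d_acts[i].T @ delta
            g_dec[i][1] = delta.sum(axis=0)
            delta = delta @ self.dec[i][0].T
        dh = delta + dh_extra
        # encoder
        delta = dh  # embedding layer is linear
        for i in reversed(range(len(self.enc))):
            if i != len(self.enc) - 1:
                # delta currently w.r.t. activation acts[i+1]
                delta = (delta + dH_extra[i]) * (pre[i] > 0)
            g_enc[i][0] = acts[i].T @ delta
            g_enc[i][1] = delta.sum(axis=0)
            delta = delta @ self.enc[i][0].T
        return [a for pair in (*g_enc, *g_dec) for a in pair]


def _normalized_adjacency(A: sp.csr_matrix) -> sp.csr_matrix:
    """D^(-1/2) (A + I) D^(-1/2), the symmetric GCN propagation operator."""
    A = A + sp.eye(A.shape[0], format="csr")
    d = np.asarray(A.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(d)
    return (sp.diags(dinv) @ A @ sp.diags(dinv)).tocsr()


def _student_t_q(h: np.ndarray, mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Soft assignments via a t-kernel with one degree of freedom."""
    d2 = ((h[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
    s = 1.0 / (1.0 + d2)
    q = s / s.sum(axis=1, keepdims=True)
    return q, s


def _target_distribution(q: np.ndarray) -> np.ndarray:
    w = q**2 / q.sum(axis=0)
    return w / w.sum(axis=1, keepdims=True)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def pretrain_autoencoder(
    features: pd.DataFrame | np.ndarray, config: SDCNConfig
) -> tuple[_Autoencoder, list[float]]:
    """Reconstruction-only pretraining; returns (model, per-epoch losses)."""
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    if not np.isfinite(X).all():
        raise DataError("features must be finite")
    rng = np.random.default_rng(config.seed)
    ae = _Autoencoder(X.shape[1], config.encoder_dims, config.embedding_dim, rng)
    opt = _Adam(ae.params(), config.learning_rate)
    n, d = X.shape
    losses = []
    zeros_H = None
    for epoch in range(config.pretrain_epochs):
        H, h, X_hat, caches = ae.forward(X)
        loss = float(((X_hat - X) ** 2).mean())
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite pretraining loss at epoch {epoch}")
        losses.append(loss)
        if zeros_H is None:
            zeros_H = [np.zeros_like(a) for a in H]
        dX_hat = 2.0 * (X_hat - X) / (n * d)
        grads = ae.backward(caches, dX_hat, np.zeros_like(h), zeros_H)
        opt.step(grads)
    return ae, losses


class _SDCNModel:
    """Joint AE + GCN model; owns all trainable parameters."""

    def __init__(self, ae: _Autoencoder, d_in: int, config: SDCNConfig, rng):
        self.ae = ae
        self.config = config
        dims = [d_in, *config.encoder_dims, config.embedding_dim, config.n_clusters]
        self.gcn = [_init_linear(rng, a, b)[0] for a, b in zip(dims, dims[1:])]
        self.mu = np.zeros((config.n_clusters, config.embedding_dim))

    def params(self):
        return [*self.ae.params(), *self.gcn, self.mu]

    def forward(self, X, A_hat):
        eps = self.config.epsilon
        H, h, X_hat, ae_caches = self.ae.forward(X)
        reps = [*H, h]  # AE representations injected layer by layer
        gcn_pre, gcn_act, mixes = [], [], []
        a = X
        for i, G in enumerate(self.gcn):
            mix = a if i == 0 else (1.0 - eps) * a + eps * reps[i - 1]
            mixes.append(mix)
            z = A_hat @ (mix @ G)
            gcn_pre.append(z)
            a = z if i == len(self.gcn) - 1 else _relu(z)
            gcn_act.append(a)
        Z = _softmax(gcn_pre[-1])
        q, s = _student_t_q(h, self.mu)
        caches = (ae_caches, H, h, X_hat, gcn_pre, gcn_act, mixes, q, s, Z)
        return caches

    def losses(self, X, P, caches):
        w_rec, w_clu, w_gcn = self.config.loss_weights
        _, _, _, X_hat, _, _, _, q, _, Z = caches
        n = X.shape[0]
        l_rec = float(((X_hat - X) ** 2).mean())
        l_clu = float((P * (np.log(P + 1e-12) - np.log(q + 1e-12))).sum() / n)
        l_gcn = float((P * (np.log(P + 1e-12) - np.log(Z + 1e-12))).sum() / n)
        return w_rec * l_rec + w_clu * l_clu + w_gcn * l_gcn, (l_rec, l_clu, l_gcn)

    def backward(self, X, A_hat, P, caches):
        w_rec, w_clu, w_gcn = self.config.loss_weights
        eps = self.config.epsilon
        ae_caches, H, h, X_hat, gcn_pre, gcn_act, mixes, q, s, Z = caches
        n, d = X.shape

        # --- GCN branch: KL(P || softmax(logits)) -> (Z - P) on logits
        dlogits = w_gcn * (Z - P) / n
        g_gcn = [np.zeros_like(G) for G in self.gcn]
        dH_extra = [np.zeros_like(a) for a in H]
        dh_gcn = np.zeros_like(h)
        delta = dlogits
        for i in reversed(range(len(self.gcn))):
            if i != len(self.gcn) - 1:
                delta = delta * (gcn_pre[i] > 0)
            dU = A_hat.T @ delta  # A_hat symmetric
            g_gcn[i] = mixes[i].T @ dU
            dmix = dU @ self.gcn[i].T
            if i == 0:
                break
            # mix = (1-eps) * act_{i-1} + eps * reps[i-1]
            if i - 1 < len(H):
                dH_extra[i - 1] += eps * dmix
            else:
                dh_gcn += eps * dmix
            delta = (1.0 - eps) * dmix

        # --- clustering branch: KL(P || Q) through the t-kernel
        # dL/dq = -w_clu * P / q / n ; q = s / srow
        dLdq = -w_clu * P / (q + 1e-12) / n
        srow = s.sum(axis=1, keepdims=True)
        dLds = (dLdq - (dLdq * q).sum(axis=1, keepdims=True)) / srow
        dLdd2 = dLds * (-(s**2))  # ds/dd2 = -s^2
        diff = h[:, None, :] - self.mu[None, :, :]
        dh_q = 2.0 * (dLdd2[:, :, None] * diff).sum(axis=1)
        dmu = -2.0 * (dLdd2[:, :, None] * diff).sum(axis=0)

        # --- reconstruction
        dX_hat = w_rec * 2.0 * (X_hat - X) / (n * d)

        g_ae = self.ae.backward(ae_caches, dX_hat, dh_q + dh_gcn, dH_extra)
        return [*g_ae, *g_gcn, dmu]

    def hard_labels(self, caches) -> np.ndarray:
        _, _, _, _, _, _, _, q, _, Z = caches
        dist = Z if self.config.head == "gcn" else q
        return dist.argmax(axis=1)


def train_sdcn(
    features: pd.DataFrame,
    graph: SampleGraph,
    config: SDCNConfig,
    pretrained: _Autoencoder | None = None,
    compute_silhouette: bool = True,
) -> ClusterAssignment:
    """Joint dual-self-supervised training; returns hard labels in 1..k.

    ``features`` should already be standardized (see
    :func:`standardize_features`).  If a cluster is empty at convergence,
    centers are re-initialized once and training repeats; a second failure
    raises :class:`TrainingError`.
    """
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    if graph.adjacency.shape[0] != n:
        raise DataError("sample graph is not aligned to the feature matrix")
    if config.n_clusters == 1:
        labels = pd.Series(np.ones(n, dtype=int), index=features.index)
        return ClusterAssignment(labels=labels, silhouette=None, average_silhouette=None, k=1)
    A_hat = _normalized_adjacency(graph.adjacency)

    if pretrained is None:
        pretrained, _ = pretrain_autoencoder(X, config)
    import copy

    for attempt in range(2):
        ae = copy.deepcopy(pretrained)
        rng = np.random.default_rng(config.seed + 1)
        model = _SDCNModel(ae, X.shape[1], config, rng)
        _, h0, _, _ = ae.forward(X)
        km = KMeans(
            n_clusters=config.n_clusters, n_init=10, random_state=config.seed + attempt
        ).fit(h0)
        model.mu[:] = km.cluster_centers_
        n_ae = len(model.ae.params())
        lrs = [config.learning_rate] * n_ae
        lrs += [config.learning_rate * config.gcn_lr_multiplier] * len(model.gcn)
        lrs += [config.learning_rate]  # cluster centers
        opt = _Adam(model.params(), config.learning_rate, lrs=lrs)
        losses = []
        for epoch in range(config.train_epochs):
            caches = model.forward(X, A_hat)
            q = caches[7]
            P = _target_distribution(q)
            loss, _ = model.losses(X, P, caches)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite SDCN loss at epoch {epoch}")
            losses.append(loss)
            grads = model.backward(X, A_hat, P, caches)
            opt.step(grads)
        caches = model.forward(X, A_hat)
        raw = model.hard_labels(caches)
        if len(np.unique(raw)) == config.n_clusters:
            break
        logger.warning("empty cluster at convergence (attempt %d); re-initializing centers", attempt + 1)
    else:
        raise TrainingError(f"empty cluster persists for k={config.n_clusters}")
    if len(np.unique(raw)) != config.n_clusters:
        raise TrainingError(f"empty cluster persists for k={config.n_clusters}")

    labels = pd.Series(raw + 1, index=features.index)
    sil = avg = None
    if compute_silhouette:
        sil, avg = _silhouette(features, labels)
    return ClusterAssignment(labels=labels, silhouette=sil, average_silhouette=avg, k=config.n_clusters, losses=losses)


def _silhouette(features: pd.DataFrame, labels: pd.Series):
    widths = silhouette_samples(features.to_numpy(dtype=float), labels.to_numpy())
    sil = pd.Series(widths, index=features.index)
    return sil, float(widths.mean())


def average_silhouette(features: pd.DataFrame, labels) -> float:
    """Mean over samples of (b - a)/max(a, b), Euclidean metric."""
    labels = np.asarray(labels)
    if features.shape[0] < 3:
        raise DataError("silhouette needs at least 3 samples")
    if len(np.unique(labels)) < 2:
        raise DataError("silhouette undefined for a single occupied cluster")
    return float(
        silhouette_samples(features.to_numpy(dtype=float), labels).mean()
    )


def select_n_clusters(
    features: pd.DataFrame,
    graph: SampleGraph,
    config: SDCNConfig,
    k_range: tuple[int, int] = (2, 10),
) -> tuple[int, ClusterAssignment, dict[int, float]]:
    """Train the network for each k in the range and keep the k with the
    highest average silhouette width.  Per-k failures are recorded and
    skipped; everything failing is an error."""
    kmin, kmax = k_range
    if kmin < 2:
        raise ParameterError("k_range.min must be >= 2")
    if features.shape[0] <= kmax:
        raise ParameterError("need more samples than k_range.max")
    pretrained, _ = pretrain_autoencoder(features.to_numpy(dtype=float), config)
    silhouettes: dict[int, float] = {}
    assignments: dict[int, ClusterAssignment] = {}
    for k in range(kmin, kmax + 1):
        cfg_k = replace(config, n_clusters=k)
        try:
            assign = train_sdcn(features, graph, cfg_k, pretrained=pretrained)
        except (TrainingError, DataError) as exc:
            logger.warning("k=%d failed: %s", k, exc)
            continue
        silhouettes[k] = assign.average_silhouette
        assignments[k] = assign
    if not assignments:
        raise TrainingError("clustering failed for every k in range")
    best_k = max(silhouettes, key=lambda k: (silhouettes[k], -k))
    return best_k, assignments[best_k], silhouettes
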