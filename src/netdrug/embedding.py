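"""Neighborhood-based gene embedding with adjacency reconstruction.

Each gene *v* gets a neighborhood N(v): its top-3 correlated genes
(first order) and the top-3 of each of those (second order, up to 9
genes, deduplicated).  A shallow network updates per-gene embedding
vectors layer by layer,

    e_v^k = sigma( W_k * mean_{u in N(v)} e_u^{k-1} + e_v^{k-1} ),

starting from the expression profile, e_v^0 = x_v.  The final vectors
z_v = e_v^K are trained so their inner products reconstruct the
co-expression adjacency:

    loss = sum_{(v, u): u in N(v)} ( z_v' z_u - A_vu )^2.

W_k is one weight matrix per layer, shared across genes; it acts on the
sample axis, so the embedding of every gene lives in the same
(sample-indexed) space as the expression matrix itself.  The learned
embedding matrix E is then a second feature source: features selected
from E and from X on the training samples are concatenated and fed to a
small fully connected ReLU regressor to predict drug response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, MLPRegressor
from .containers import ExpressionMatrix
from .network import CoexpressionNetwork
from .selection import select_top_k

__all__ = [
    "NeighborhoodSpec",
    "EmbedTrainConfig",
    "build_neighborhood",
    "neighborhood_matrix",
    "embed_update",
    "embed_forward",
    "embed_loss",
    "train_embeddings",
    "predict_from_embeddings",
]


@dataclass
class NeighborhoodSpec:
    """First- and second-order neighbor indices of one target gene."""

    target: int
    first_order: list[int]
    second_order: list[int]

    @property
    def members(self) -> list[int]:
        """N(v): the union of both orders, target excluded."""
        return self.first_order + self.second_order


@dataclass
class EmbedTrainConfig:
    K: int = 2
    activation: str = "tanh"  # "tanh" | "relu" | "identity"
    epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0
    normalize_inputs: bool = True

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


_ACTIVATIONS = {
    "tanh": (np.tanh, lambda z, a: 1.0 - a * a),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(float)),
    "identity": (lambda z: z, lambda z, a: np.ones_like(z)),
}


def _top3(A_row: np.ndarray, gene_ids: list[str], exclude: int) -> list[int]:
    idx = [i for i in range(len(gene_ids)) if i != exclude]
    idx.sort(key=lambda i: (-A_row[i], gene_ids[i]))
    return idx[:3]


def build_neighborhood(net: CoexpressionNetwork, v: int) -> NeighborhoodSpec:
    """Top-3 / top-3-of-top-3 neighborhood of gene ``v``.

    Second-order candidates that coincide with the target or a first-order
    neighbor (or repeat each other) are deduplicated, so the second-order
    list holds at most nine distinct genes.  Correlation ties break toward
    the lexicographically smaller gene id.
    """
    m = net.n_genes
    if m < 4:
        raise ValueError("need at least 4 genes to form a first-order neighborhood")
    first = _top3(net.A[v], net.gene_ids, exclude=v)
    second: list[int] = []
    seen = {v, *first}
    for u in first:
        for w in _top3(net.A[u], net.gene_ids, exclude=u):
            if w not in seen:
                second.append(w)
                seen.add(w)
    return NeighborhoodSpec(target=v, first_order=first, second_order=second)


def neighborhood_matrix(specs: list[NeighborhoodSpec], m: int) -> np.ndarray:
    """Row-stochastic averaging matrix: row v holds 1/|N(v)| on N(v)."""
    N = np.zeros((m, m))
    for s in specs:
        members = s.members
        N[s.target, members] = 1.0 / len(members)
    return N


def embed_update(
    e_prev: np.ndarray, spec: NeighborhoodSpec, W_k: np.ndarray, activation: str = "tanh"
) -> np.ndarray:
    """One-layer update of a single gene's embedding vector.

    ``e_prev`` holds the previous-layer embeddings of all genes (m x n);
    returns sigma(W_k @ mean of N(v) rows + previous own row).
    """
    e_prev = np.asarray(e_prev, dtype=float)
    mean_nb = e_prev[spec.members].mean(axis=0)
    if W_k.shape[1] != mean_nb.shape[0]:
        raise ValueError(
            f"weight shape {W_k.shape} incompatible with embedding width {mean_nb.shape[0]}"
        )
    act, _ = _ACTIVATIONS[activation]
    return act(W_k @ mean_nb + e_prev[spec.target])


def embed_forward(
    E0: np.ndarray, N: np.ndarray, weights: list[np.ndarray], activation: str,
    caches: list | None = None,
) -> np.ndarray:
    """All-gene forward pass through K layers (vectorized embed_update)."""
    act, _ = _ACTIVATIONS[activation]
    E = E0
    for W in weights:
        pre = (N @ E) @ W.T + E
        E_next = act(pre)
        if caches is not None:
            caches.append((E, pre, E_next))
        E = E_next
    return E


def embed_loss(
    Z: np.ndarray, net: CoexpressionNetwork, pairs: list[tuple[int, int]]
) -> float:
    """Adjacency-reconstruction loss over the configured (target, neighbor) pairs."""
    total = 0.0
    for v, u in pairs:
        r = float(Z[v] @ Z[u]) - net.A[v, u]
        total += r * r
    return total


def _pair_set(specs: list[NeighborhoodSpec]) -> list[tuple[int, int]]:
    return [(s.target, u) for s in specs for u in s.members]


def train_embeddings(
    x: ExpressionMatrix,
    net: CoexpressionNetwork,
    cfg: EmbedTrainConfig | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Fit the shared layer weights by gradient descent on the reconstruction loss.

    Returns the embedding matrix E (same shape as the expression matrix)
    and the per-epoch loss history.  With ``normalize_inputs`` (default)
    the starting embeddings are the z-scored expression rows divided by
    sqrt(n), so initial inner products equal signed Pearson correlations —
    the same scale as the adjacency being reconstructed.
    """
    cfg = cfg or EmbedTrainConfig()
    if x.n_genes != net.n_genes:
        raise ValueError("expression and network gene sets differ")
    m, n = x.values.shape
    E0 = x.values.astype(float)
    if cfg.normalize_inputs:
        E0 = (E0 - E0.mean(axis=1, keepdims=True))
        sd = E0.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        E0 = E0 / sd / np.sqrt(n)

    specs = [build_neighborhood(net, v) for v in range(m)]
    N = neighborhood_matrix(specs, m)
    pairs = _pair_set(specs)
    pv = np.array([p[0] for p in pairs])
    pu = np.array([p[1] for p in pairs])
    a = net.A[pv, pu]

    rng = np.random.default_rng(cfg.seed)
    weights = [rng.normal(0.0, 0.01 / np.sqrt(n), size=(n, n)) for _ in range(cfg.K)]
    opt = Adam(weights, lr=cfg.learning_rate)
    _, dact = _ACTIVATIONS[cfg.activation]

    history: list[float] = []
    for _ in range(cfg.epochs):
        caches: list = []
        Z = embed_forward(E0, N, weights, cfg.activation, caches)
        resid = np.einsum("ij,ij->i", Z[pv], Z[pu]) - a
        loss = float(resid @ resid)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite embedding loss; lower the learning rate")
        history.append(loss)
        if cfg.learning_rate <= 0:
            continue
        # dL/dZ: row v gains 2r*z_u, row u gains 2r*z_v, per pair
        R = np.zeros((m, m))
        np.add.at(R, (pv, pu), 2.0 * resid)
        dE = R @ Z + R.T @ Z
        grads = [np.zeros_like(W) for W in weights]
        for k in range(cfg.K - 1, -1, -1):
            E_in, pre, E_out = caches[k]
            dpre = dE * dact(pre, E_out)
            grads[k] = dpre.T @ (N @ E_in)
            dE = N.T @ (dpre @ weights[k]) + dpre
        opt.step(grads)

    Z = embed_forward(E0, N, weights, cfg.activation)
    return Z, history


@dataclass
class FCHeadConfig:
    hidden: int = 64
    epochs: int = 300
    learning_rate: float = 1e-2
    seed: int = 0


def _abs_corr(rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = rows - rows.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(yc)
    denom[denom == 0] = np.inf
    return np.abs(xc @ yc / denom)


def predict_from_embeddings(
    E: np.ndarray,
    x: ExpressionMatrix,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    k_features: int = 100,
    fc_cfg: FCHeadConfig | None = None,
) -> np.ndarray:
    """Select features from E and X on training samples, regress, predict test.

    ``y`` need only be defined on ``train_idx``; test labels are never
    touched — selection scores and the regressor see the training
    partition only.
    """
    fc_cfg = fc_cfg or FCHeadConfig()
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    y_train = np.asarray(y, dtype=float)[train_idx]
    k = min(k_features, x.n_genes)

    picked = []
    for source in (E, x.values):
        scores = _abs_corr(source[:, train_idx], y_train)
        sel = select_top_k(scores, x.gene_ids, k)
        rows = [x.gene_ids.index(g) for g in sel.selected_gene_ids]
        picked.append(source[rows])
    feats = np.vstack(picked).T  # samples x (2k)

    mu = feats[train_idx].mean(axis=0)
    sd = feats[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    feats = (feats - mu) / sd

    head = MLPRegressor(feats.shape[1], hidden=(fc_cfg.hidden,), seed=fc_cfg.seed)
    head.fit(feats[train_idx], y_train, epochs=fc_cfg.epochs, lr=fc_cfg.learning_rate)
    return head.predict(feats[test_idx])
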