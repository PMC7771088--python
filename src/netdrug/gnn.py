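"""Graph convolutional regressor over the gene co-expression network.

Propagation follows the renormalized rule

    H^k = sigma( P H^{k-1} W^{k-1} ),      P = D~^{-1/2} (A + I) D~^{-1/2},

with H^0 the expression values: each cell line is one graph signal, its
node features the per-gene expression scalars, so H^0 is (samples, genes,
1) and the widths in ``layer_dims`` act on the feature axis.  A readout
head maps the final node features to one response value per cell line —
by default a learned linear layer over gene-averaged node features
("mean_pool"); a per-gene learned linear head over feature-averaged H^K
("linear") is available but overfits small cell-line panels.  Training
minimizes MSE with Adam; ReLU hidden activations.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from ._nn import Adam
from .containers import ExpressionMatrix
from .network import CoexpressionNetwork, gcn_operator

__all__ = ["GNNConfig", "GCNRegressor", "gcn_forward", "train_gnn"]


@dataclass
class GNNConfig:
    layer_dims: list[int] = field(default_factory=lambda: [64, 64])
    activation: str = "relu"
    epochs: int = 300
    learning_rate: float = 1e-2
    seed: int = 0
    readout: str = "mean_pool"  # "mean_pool" (over genes) or "linear" (learned, over genes)

    def __post_init__(self) -> None:
        if len(self.layer_dims) < 1 or any(d < 1 for d in self.layer_dims):
            raise ValueError("layer_dims must hold positive widths")
        if self.activation not in ("relu", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.readout not in ("linear", "mean_pool"):
            raise ValueError(f"unknown readout {self.readout!r}")


def gcn_forward(
    x: ExpressionMatrix,
    net: CoexpressionNetwork,
    cfg: GNNConfig,
    weights: list[np.ndarray],
    caches: list | None = None,
    P: np.ndarray | None = None,
) -> np.ndarray:
    """Propagate expression through the GCN stack.

    Returns H^K of shape (n_samples, n_genes, layer_dims[-1]).  ``weights``
    must chain from width 1 through ``cfg.layer_dims``.
    """
    if P is None:
        P = gcn_operator(net)
    dims = [1, *cfg.layer_dims]
    for k, W in enumerate(weights):
        if W.shape != (dims[k], dims[k + 1]):
            raise ValueError(
                f"layer {k} weight shape {W.shape} != expected {(dims[k], dims[k + 1])}"
            )
    H = x.values.T[:, :, None]  # (n, m, 1)
    last = len(weights) - 1
    for k, W in enumerate(weights):
        pre = np.matmul(P, H) @ W
        H_next = np.maximum(pre, 0.0) if cfg.activation == "relu" else pre
        if caches is not None:
            caches.append((H, pre, H_next))
        H = H_next
    return H


class GCNRegressor:
    """GCN stack plus readout head, trained end to end on one drug."""

    def __init__(self, n_genes: int, cfg: GNNConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dims = [1, *cfg.layer_dims]
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / dims[k]), size=(dims[k], dims[k + 1]))
            for k in range(len(cfg.layer_dims))
        ]
        if cfg.readout == "linear":
            self.w_out = rng.normal(0.0, 1.0 / np.sqrt(n_genes), size=n_genes)
        else:
            self.w_out = rng.normal(0.0, 1.0 / np.sqrt(dims[-1]), size=dims[-1])
        self.b_out = 0.0

    # -- forward -------------------------------------------------------
    def _readout(self, H: np.ndarray) -> np.ndarray:
        if self.cfg.readout == "linear":
            pooled = H.mean(axis=2)  # (n, m): average over feature width
            return pooled @ self.w_out + self.b_out
        pooled = H.mean(axis=1)  # (n, d): average over genes
        return pooled @ self.w_out + self.b_out

    def predict(self, x: ExpressionMatrix, net: CoexpressionNetwork,
                P: np.ndarray | None = None) -> np.ndarray:
        return self._readout(gcn_forward(x, net, self.cfg, self.weights, P=P))

    # -- training ------------------------------------------------------
    def fit(
        self,
        x: ExpressionMatrix,
        y: np.ndarray,
        net: CoexpressionNetwork,
        train_idx: np.ndarray,
        P: np.ndarray | None = None,
    ) -> list[float]:
        """Full-batch Adam on MSE over the training samples; loss history returned."""
        if P is None:
            P = gcn_operator(net)
        cfg = self.cfg
        train_idx = np.asarray(train_idx)
        x_train = x.subset_samples(train_idx)
        y_train = np.asarray(y, dtype=float)[train_idx]
        n = len(y_train)
        params = [*self.weights, self.w_out]
        opt = Adam(params, lr=cfg.learning_rate)
        history: list[float] = []
        for _ in range(cfg.epochs):
            caches: list = []
            H = gcn_forward(x_train, net, cfg, self.weights, caches=caches, P=P)
            pred = self._readout(H)
            resid = pred - y_train
            loss = float(resid @ resid / n)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite GCN training loss")
            history.append(loss)
            if cfg.learning_rate <= 0:
                continue
            d_pred = 2.0 * resid / n  # (n,)
            if cfg.readout == "linear":
                pooled = H.mean(axis=2)
                g_wout = pooled.T @ d_pred
                dH = (d_pred[:, None] * self.w_out[None, :])[:, :, None] / H.shape[2]
                dH = np.broadcast_to(dH, H.shape).copy()
            else:
                pooled = H.mean(axis=1)
                g_wout = pooled.T @ d_pred
                dH = (d_pred[:, None] * self.w_out[None, :])[:, None, :] / H.shape[1]
                dH = np.broadcast_to(dH, H.shape).copy()
            g_bout = float(d_pred.sum())
            grads = [np.zeros_like(W) for W in self.weights]
            for k in range(len(self.weights) - 1, -1, -1):
                H_in, pre, _ = caches[k]
                dpre = dH * (pre > 0) if cfg.activation == "relu" else dH
                PH = np.matmul(P, H_in)  # (n, m, d_in)
                grads[k] = np.einsum("nmd,nme->de", PH, dpre)
                dH = np.matmul(P.T, dpre @ self.weights[k].T)
            opt.step([*grads, g_wout])
            self.b_out -= cfg.learning_rate * g_bout
        return history

    # -- persistence ---------------------------------------------------
    def save(self, path: str) -> None:
        """Text checkpoint: JSON manifest with flattened weights."""
        payload = {
            "config": asdict(self.cfg),
            "weights": [W.tolist() for W in self.weights],
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "GCNRegressor":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = GNNConfig(**payload["config"])
        w_out = np.asarray(payload["w_out"])
        n_genes = len(w_out) if cfg.readout == "linear" else 1
        model = cls(max(n_genes, 1), cfg)
        model.weights = [np.asarray(W) for W in payload["weights"]]
        model.w_out = w_out
        model.b_out = float(payload["b_out"])
        return model


def train_gnn(
    x: ExpressionMatrix,
    y: np.ndarray,
    net: CoexpressionNetwork,
    cfg: GNNConfig,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    standardize: bool = True,
) -> tuple[GCNRegressor, np.ndarray]:
    """Train on the training partition, return (model, test predictions).

    With ``standardize`` (default) gene rows are z-scored and the response
    centered using training-sample statistics only; predictions are mapped
    back to the response scale.  Correlations are unaffected, optimization
    is far better conditioned.
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    y = np.asarray(y, dtype=float)
    y_shift = 0.0
    if standardize:
        mu = x.values[:, train_idx].mean(axis=1, keepdims=True)
        sd = x.values[:, train_idx].std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = ExpressionMatrix((x.values - mu) / sd, x.gene_ids, x.sample_ids)
        y_shift = float(y[train_idx].mean())
        y = y - y_shift
    P = gcn_operator(net)
    model = GCNRegressor(x.n_genes, cfg)
    model.fit(x, y, net, train_idx, P=P)
    preds = model.predict(x.subset_samples(test_idx), net, P=P)
    return model, preds + y_shift
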