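"""Canonical regression baselines behind one fit/predict contract.

Five models with fixed hyperparameters (no validation-set tuning):

* ``random_forest`` — 500 trees, 50 candidate features per split,
  regression-mode forest (mean of tree predictions);
* ``elastic_net`` — L1 ratio 0.5, penalty strength 0.1;
* ``svr`` — RBF kernel, C = 1, gamma = 1 / (n_features * Var(X));
* ``plsr`` — one latent component;
* ``dnn`` — two ReLU hidden layers trained on MSE, linear output unit
  (a literal softmax output is available but is constant for a scalar
  target, hence useless for regression — kept only for comparison runs).

All accept identically shaped (samples x features) matrices and return
one prediction per test sample; seeded models are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet
from sklearn.svm import SVR

from ._nn import MLPRegressor

__all__ = ["BaselineSpec", "BASELINE_DEFAULTS", "fit_predict", "dnn_fit_predict"]

BASELINE_DEFAULTS: dict[str, dict[str, Any]] = {
    "random_forest": {"n_trees": 500, "max_features": 50},
    "elastic_net": {"l1_ratio": 0.5, "lam": 0.1},
    "svr": {"C": 1.0, "epsilon": 0.1},  # gamma = 1/(n_features * Var(X)) i.e. sklearn "scale"
    "plsr": {"n_components": 1},
    "dnn": {"hidden": (64, 64), "epochs": 300, "learning_rate": 1e-3, "output": "linear"},
}


@dataclass
class BaselineSpec:
    name: str
    hyperparams: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in BASELINE_DEFAULTS:
            raise ValueError(
                f"unknown baseline {self.name!r}; choose from {sorted(BASELINE_DEFAULTS)}"
            )
        merged = dict(BASELINE_DEFAULTS[self.name])
        unknown = set(self.hyperparams) - set(merged)
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.name}: {sorted(unknown)}")
        merged.update(self.hyperparams)
        self.hyperparams = merged


def dnn_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    hidden: tuple[int, ...] = (64, 64),
    epochs: int = 300,
    learning_rate: float = 1e-3,
    output: str = "linear",
    seed: int = 0,
) -> np.ndarray:
    """Two-hidden-layer feed-forward regressor; features z-scored on train stats."""
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    mu, sd = X_train.mean(axis=0), X_train.std(axis=0)
    sd[sd == 0] = 1.0
    net = MLPRegressor(X_train.shape[1], hidden=tuple(hidden), output=output, seed=seed)
    net.fit((X_train - mu) / sd, y_train, epochs=epochs, lr=learning_rate)
    return net.predict((X_test - mu) / sd)


def fit_predict(
    spec: BaselineSpec, X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray
) -> np.ndarray:
    """Fit the named baseline on the training partition and predict the test one."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("train/test feature widths differ")
    hp = spec.hyperparams
    name = spec.name
    if name == "random_forest":
        model = RandomForestRegressor(
            n_estimators=hp["n_trees"],
            max_features=min(hp["max_features"], X_train.shape[1]),
            random_state=spec.seed,
        )
    elif name == "elastic_net":
        model = ElasticNet(alpha=hp["lam"], l1_ratio=hp["l1_ratio"], max_iter=10000)
    elif name == "svr":
        model = SVR(kernel="rbf", C=hp["C"], epsilon=hp["epsilon"], gamma="scale")
    elif name == "plsr":
        if X_train.shape[0] <= hp["n_components"]:
            raise ValueError(
                f"PLSR needs more training samples than components "
                f"({X_train.shape[0]} <= {hp['n_components']})"
            )
        model = PLSRegression(n_components=hp["n_components"])
    elif name == "dnn":
        return dnn_fit_predict(X_train, y_train, X_test, seed=spec.seed,
                               **{k: hp[k] for k in ("hidden", "epochs", "learning_rate", "output")})
    model.fit(X_train, y_train)
    return np.ravel(model.predict(X_test))
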