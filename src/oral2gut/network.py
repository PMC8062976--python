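"""The predictive model: a small fully-connected regression network.

Architecture: two ReLU hidden layers (50 units each by default) with
dropout, and a linear output layer with one unit per predicted feature (12
families + "Other" = 13) and no activation. Training minimizes mean squared
error plus an L2 weight penalty with Adam; mean absolute error on the percent
scale is the monitoring metric. The stopping epoch is chosen by k-fold
cross-validation: the fold-averaged validation MAE is recorded after every
epoch and the model is refitted on all training samples for the argmin epoch.

Everything is implemented directly on numpy; the network is small enough
(~5k parameters) that explicit backpropagation is both fast and exactly
reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold


@dataclass
class NetworkConfig:
    """Hyperparameters of the network and its training protocol."""

    n_inputs: int
    hidden_sizes: tuple[int, ...] = (50, 50)
    n_outputs: int = 13
    l2_coeff: float = 0.001
    dropout_rate: float = 0.5
    epochs: int = 500
    k_folds: int = 4
    learning_rate: float = 0.001
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_outputs < 1:
            raise ValueError("n_inputs and n_outputs must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_coeff < 0:
            raise ValueError("l2_coeff must be nonnegative")
        if self.epochs < 1 or self.k_folds < 2:
            raise ValueError("epochs >= 1 and k_folds >= 2 required")


@dataclass
class CVCurve:
    """Fold-averaged validation MAE per epoch and its (1-based) argmin."""

    per_epoch_mae: np.ndarray
    best_epoch: int

    def __post_init__(self) -> None:
        self.per_epoch_mae = np.asarray(self.per_epoch_mae, dtype=float)
        if not 1 <= self.best_epoch <= len(self.per_epoch_mae):
            raise ValueError("best_epoch out of range")

    @property
    def best_mae(self) -> float:
        return float(self.per_epoch_mae[self.best_epoch - 1])


@dataclass
class TrainedNetwork:
    """Fitted weights plus the config and stopping epoch they came from.

    ``weights`` / ``biases`` are per-layer arrays, input to output. The
    preprocessing state (feature set, scaler, schema) is attached by the
    pipeline when the network is bundled.
    """

    config: NetworkConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    best_epoch: int
    feature_set: object | None = None
    scaler: object | None = None
    schema: object | None = None


def kfold_split(n_samples: int, k: int, seed: int) -> list[np.ndarray]:
    """Shuffled k-fold partition of ``range(n_samples)``; sizes differ by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_samples:
        raise ValueError(f"k={k} exceeds n_samples={n_samples}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [val_idx for _, val_idx in kf.split(np.arange(n_samples))]


def _init_params(
    config: NetworkConfig, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    sizes = [config.n_inputs, *config.hidden_sizes, config.n_outputs]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        # He initialization, appropriate for the ReLU hidden stack
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _forward_inference(
    weights: list[np.ndarray], biases: list[np.ndarray], X: np.ndarray
) -> np.ndarray:
    h = X
    for W, b in zip(weights[:-1], biases[:-1]):
        h = np.maximum(h @ W + b, 0.0)
    return h @ weights[-1] + biases[-1]


class _AdamState:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def _train(
    X: np.ndarray,
    Y: np.ndarray,
    config: NetworkConfig,
    rng: np.random.Generator,
    epochs: int,
    X_val: Optional[np.ndarray] = None,
    Y_val: Optional[np.ndarray] = None,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Run the training loop; returns (weights, biases, per-epoch val MAE)."""
    weights, biases = _init_params(config, rng)
    params = weights + biases
    opt = _AdamState(params, config.learning_rate)
    n = X.shape[0]
    n_hidden = len(config.hidden_sizes)
    val_mae = np.full(epochs, np.nan)
    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], Y[idx]
            b = len(idx)
            # forward with inverted dropout on the hidden layers
            acts = [xb]
            masks = []
            h = xb
            for li in range(n_hidden):
                h = np.maximum(h @ weights[li] + biases[li], 0.0)
                if config.dropout_rate > 0:
                    mask = (
                        rng.random(h.shape) >= config.dropout_rate
                    ) / (1.0 - config.dropout_rate)
                    h = h * mask
                else:
                    mask = None
                masks.append(mask)
                acts.append(h)
            out = h @ weights[-1] + biases[-1]
            # backward: MSE over all entries + L2 on weights
            delta = (2.0 / (b * config.n_outputs)) * (out - yb)
            w_grads: list[np.ndarray] = [None] * len(weights)
            b_grads: list[np.ndarray] = [None] * len(biases)
            w_grads[-1] = acts[-1].T @ delta + 2 * config.l2_coeff * weights[-1]
            b_grads[-1] = delta.sum(axis=0)
            upstream = delta @ weights[-1].T
            for li in range(n_hidden - 1, -1, -1):
                if masks[li] is not None:
                    upstream = upstream * masks[li]
                # ReLU gate: post-dropout activation > 0 iff pre-ReLU > 0
                upstream = upstream * (acts[li + 1] > 0)
                w_grads[li] = acts[li].T @ upstream + 2 * config.l2_coeff * weights[li]
                b_grads[li] = upstream.sum(axis=0)
                if li > 0:
                    upstream = upstream @ weights[li].T
            opt.step(params, w_grads + b_grads)
        if X_val is not None:
            pred = _forward_inference(weights, biases, X_val)
            val_mae[epoch] = np.abs(pred - Y_val).mean()
    return weights, biases, val_mae


def _validate_training_inputs(X: np.ndarray, Y: np.ndarray, config: NetworkConfig):
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if X.shape[1] != config.n_inputs:
        raise ValueError(
            f"X has {X.shape[1]} columns, config expects {config.n_inputs}"
        )
    if Y.shape[1] != config.n_outputs:
        raise ValueError(
            f"Y has {Y.shape[1]} columns, config expects {config.n_outputs}"
        )
    if not np.isfinite(X).all() or not np.isfinite(Y).all():
        raise ValueError("non-finite values in training inputs")
    return X, Y


def train_cv(X: np.ndarray, Y: np.ndarray, config: NetworkConfig) -> CVCurve:
    """K-fold cross-validation: fold-averaged validation MAE per epoch.

    Each fold trains a fresh network on the other k-1 folds and records
    validation MAE after every epoch; the curve is the mean over folds and
    ``best_epoch`` its earliest argmin.
    """
    X, Y = _validate_training_inputs(X, Y, config)
    folds = kfold_split(X.shape[0], config.k_folds, config.seed)
    curves = np.zeros((config.k_folds, config.epochs))
    all_idx = np.arange(X.shape[0])
    for fi, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, val_idx)
        rng = np.random.default_rng([config.seed, 1 + fi])
        _, _, val_mae = _train(
            X[train_idx],
            Y[train_idx],
            config,
            rng,
            config.epochs,
            X[val_idx],
            Y[val_idx],
        )
        curves[fi] = val_mae
    mean_curve = curves.mean(axis=0)
    best_epoch = int(np.argmin(mean_curve)) + 1  # earliest on ties
    return CVCurve(mean_curve, best_epoch)


def fit_final(
    X: np.ndarray, Y: np.ndarray, config: NetworkConfig, best_epoch: int
) -> TrainedNetwork:
    """Refit on all samples for exactly ``best_epoch`` epochs."""
    if best_epoch < 1:
        raise ValueError("best_epoch must be >= 1")
    X, Y = _validate_training_inputs(X, Y, config)
    rng = np.random.default_rng([config.seed, 0])
    weights, biases, _ = _train(X, Y, config, rng, best_epoch)
    return TrainedNetwork(config, weights, biases, best_epoch)


def predict_raw(model: TrainedNetwork, X_new: np.ndarray) -> np.ndarray:
    """Deterministic forward pass (dropout off); no clipping or rescaling.

    Outputs are on the percent scale and may be negative; post-processing
    turns them into valid compositions.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.config.n_inputs:
        raise ValueError(
            f"expected {model.config.n_inputs} input columns, got shape "
            f"{X_new.shape}"
        )
    return _forward_inference(model.weights, model.biases, X_new)


class CrossValidatedMLP(RegressorMixin, BaseEstimator):
    """Sklearn-style estimator around the CV-selected-epoch network.

    ``fit`` runs the full protocol (k-fold CV to pick the stopping epoch,
    then a refit on all samples); ``predict`` returns raw percent-scale
    outputs. Fitted attributes: ``cv_curve_``, ``best_epoch_``, ``network_``.
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = (50, 50),
        l2_coeff: float = 0.001,
        dropout_rate: float = 0.5,
        epochs: int = 500,
        k_folds: int = 4,
        learning_rate: float = 0.001,
        batch_size: int = 16,
        seed: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.l2_coeff = l2_coeff
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.k_folds = k_folds
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed

    def _make_config(self, X: np.ndarray, Y: np.ndarray) -> NetworkConfig:
        return NetworkConfig(
            n_inputs=X.shape[1],
            hidden_sizes=tuple(self.hidden_sizes),
            n_outputs=Y.shape[1],
            l2_coeff=self.l2_coeff,
            dropout_rate=self.dropout_rate,
            epochs=self.epochs,
            k_folds=self.k_folds,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            seed=self.seed,
        )

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "CrossValidatedMLP":
        config = self._make_config(np.asarray(X), np.asarray(Y))
        self.config_ = config
        self.cv_curve_ = train_cv(X, Y, config)
        self.best_epoch_ = self.cv_curve_.best_epoch
        self.network_ = fit_final(X, Y, config, self.best_epoch_)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_raw(self.network_, X)
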