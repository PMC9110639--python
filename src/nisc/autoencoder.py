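"""Denoising autoencoder with a dropout-probability-weighted loss.

The network maps each cell (a length-G vector of log1p expression values)
through three hidden layers of widths (2G, ceil(G/2), 2G) back to G outputs.
Hidden layers use ReLU; the output layer uses softplus so that the
reconstruction stays strictly positive and its inverse log transform is
always defined. Training minimizes

    sum_ij w_ij * (zhat_ij - z_ij)^2  +  alpha * ||beta||^2

where z = log1p(y), w_ij = 1 - P_ij is the complement of the Michaelis-Menten
dropout probability (exactly 0 at observed zeros, so those reconstruction
terms never contribute), and ||beta||^2 sums the squared connection weights
(biases excluded). Optimization is Adam on shuffled mini-batches of cells,
with inverted-dropout regularization on the hidden activations. Everything is
plain numpy: with a fixed seed, two runs are bitwise identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import ExpressionMatrix
from .mmk_dropout import DropoutModel

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "TrainResult",
    "build_network",
    "weighted_loss",
    "train",
    "select_alpha",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the autoencoder.

    hidden_sizes defaults to (2G, ceil(G/2), 2G): the encoder/decoder layers
    are twice the number of genes and the bottleneck is half of it.
    """

    n_genes: int
    hidden_sizes: tuple[int, int, int]
    activation: str = "relu"
    dropout_rate: float = 0.2

    def layer_sizes(self) -> list[int]:
        return [self.n_genes, *self.hidden_sizes, self.n_genes]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    alpha is the L2 regularization rate on connection weights. Early
    stopping compares the mean full-data loss over the last ``patience``
    epochs with the mean over the preceding ``patience`` epochs and stops
    once the relative improvement falls below ``tol``; window means are used
    because the sum-reduced loss oscillates under constant-rate Adam while
    its trend is still falling. ``patience=0`` disables early stopping.
    """

    alpha: float = 1e-4
    learning_rate: float = 1e-3
    max_epochs: int = 1000
    batch_size: int = 64
    patience: int = 100
    tol: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.tol < 0 or self.patience < 0 or self.max_epochs < 1:
            raise ValueError("tol/patience must be >= 0 and max_epochs >= 1")


class MLPParams:
    """Weights and biases of the network (the beta of the penalty term)."""

    def __init__(self, weights: list[np.ndarray], biases: list[np.ndarray]):
        self.weights = weights
        self.biases = biases

    def squared_weight_norm(self) -> float:
        """sum of all squared connection weights; biases excluded."""
        return float(sum(np.sum(W * W) for W in self.weights))

    def copy(self) -> "MLPParams":
        return MLPParams([W.copy() for W in self.weights], [b.copy() for b in self.biases])


@dataclass
class TrainResult:
    """Trained parameters plus the per-epoch full-data loss trace."""

    model: MLPParams
    loss_history: list[float]
    epochs_run: int
    spec: NetworkSpec
    config: TrainConfig

    def __post_init__(self):
        assert self.epochs_run == len(self.loss_history)


def build_network(n_genes: int, dropout_rate: float = 0.2) -> NetworkSpec:
    """Default architecture: hidden widths (2G, ceil(G/2), 2G) for G genes."""
    if n_genes < 2:
        raise ValueError(f"need at least 2 genes, got {n_genes}")
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    g = int(n_genes)
    return NetworkSpec(
        n_genes=g,
        hidden_sizes=(2 * g, math.ceil(g / 2), 2 * g),
        activation="relu",
        dropout_rate=dropout_rate,
    )


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _init_params(spec: NetworkSpec, rng: np.random.Generator) -> MLPParams:
    sizes = spec.layer_sizes()
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / fan_in)  # He init for the ReLU stack
        weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPParams(weights, biases)


def _forward(
    params: MLPParams,
    Z: np.ndarray,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Forward pass on (n_cells, G) input; returns output and layer caches."""
    a = Z
    pre, post, masks = [], [Z], []
    n_layers = len(params.weights)
    for ell, (W, b) in enumerate(zip(params.weights, params.biases)):
        s = a @ W + b
        pre.append(s)
        if ell < n_layers - 1:
            a = np.maximum(s, 0.0)
            if dropout_rate > 0.0 and rng is not None:
                mask = (rng.random(a.shape) >= dropout_rate) / (1.0 - dropout_rate)
                a = a * mask
            else:
                mask = None
            masks.append(mask)
        else:
            a = _softplus(s)
        post.append(a)
    return a, pre, post, masks


def predict_log1p(params: MLPParams, Z: np.ndarray) -> np.ndarray:
    """Deterministic (no-dropout) reconstruction in log1p space."""
    out, *_ = _forward(params, Z)
    return out


def weighted_loss(y_hat, y, weight, alpha: float = 0.0, params=None) -> float:
    """The training objective on expression-scale matrices.

    sum_ij weight_ij * (log1p(yhat_ij) - log1p(y_ij))^2 + alpha * ||beta||^2.
    Entries with weight 0 contribute exactly 0 regardless of the prediction
    there; the penalty sums squared connection weights only.
    """
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    weight = np.asarray(weight, dtype=float)
    if y_hat.shape != y.shape or weight.shape != y.shape:
        raise ValueError(
            f"shape mismatch: y_hat {y_hat.shape}, y {y.shape}, weight {weight.shape}"
        )
    if np.any(weight < 0):
        raise ValueError("weights must be non-negative")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    diff = np.log1p(y_hat) - np.log1p(y)
    recon = float(np.sum(weight * np.where(weight > 0, diff, 0.0) ** 2))
    penalty = 0.0
    if alpha > 0 and params is not None:
        sq = (
            params.squared_weight_norm()
            if hasattr(params, "squared_weight_norm")
            else float(sum(np.sum(np.asarray(W) ** 2) for W in params))
        )
        penalty = alpha * sq
    return recon + penalty


def _full_loss(params: MLPParams, Z: np.ndarray, W_loss: np.ndarray, alpha: float) -> float:
    out = predict_log1p(params, Z)
    recon = float(np.sum(W_loss * (out - Z) ** 2))
    return recon + alpha * params.squared_weight_norm()


def _coerce_training_arrays(matrix, dropout_model):
    v = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, dtype=float)
    w = dropout_model.weight if isinstance(dropout_model, DropoutModel) else np.asarray(dropout_model)
    if w.shape != v.shape:
        raise ValueError(f"weight shape {w.shape} does not match matrix shape {v.shape}")
    # cells become rows (training examples)
    return np.log1p(v).T, np.asarray(w, dtype=float).T


def train(
    matrix,
    dropout_model,
    spec: NetworkSpec | None = None,
    config: TrainConfig | None = None,
) -> TrainResult:
    """Train the autoencoder on a genes x cells matrix.

    Each cell (column) is one training example presented as log1p(counts).
    Mini-batches are reshuffled every epoch with a generator seeded from
    ``config.seed``; training stops early when the windowed mean of the
    full-data loss plateaus (see :class:`TrainConfig`).
    """
    Z, W_loss = _coerce_training_arrays(matrix, dropout_model)
    n_cells, n_genes = Z.shape
    if spec is None:
        spec = build_network(n_genes)
    if spec.n_genes != n_genes:
        raise ValueError(f"spec built for {spec.n_genes} genes, matrix has {n_genes}")
    if config is None:
        config = TrainConfig()
    batch_size = min(config.batch_size, n_cells)

    rng = np.random.default_rng(config.seed)
    params = _init_params(spec, rng)
    n_layers = len(params.weights)

    # Adam state
    mW = [np.zeros_like(W) for W in params.weights]
    vW = [np.zeros_like(W) for W in params.weights]
    mb = [np.zeros_like(b) for b in params.biases]
    vb = [np.zeros_like(b) for b in params.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    loss_history: list[float] = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(n_cells)
        for start in range(0, n_cells, batch_size):
            idx = order[start : start + batch_size]
            Zb, Wb = Z[idx], W_loss[idx]
            out, pre, post, masks = _forward(params, Zb, spec.dropout_rate, rng)

            # d loss / d output, then back through softplus
            g = 2.0 * Wb * (out - Zb)
            delta = g * (1.0 / (1.0 + np.exp(-pre[-1])))  # softplus' = sigmoid
            gradW = [None] * n_layers
            gradb = [None] * n_layers
            for ell in range(n_layers - 1, -1, -1):
                gradW[ell] = post[ell].T @ delta + 2.0 * config.alpha * params.weights[ell]
                gradb[ell] = delta.sum(axis=0)
                if ell > 0:
                    delta = delta @ params.weights[ell].T
                    if masks[ell - 1] is not None:
                        delta = delta * masks[ell - 1]
                    delta = delta * (pre[ell - 1] > 0)

            t += 1
            lr_t = config.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
            for ell in range(n_layers):
                mW[ell] = beta1 * mW[ell] + (1 - beta1) * gradW[ell]
                vW[ell] = beta2 * vW[ell] + (1 - beta2) * gradW[ell] ** 2
                params.weights[ell] -= lr_t * mW[ell] / (np.sqrt(vW[ell]) + eps)
                mb[ell] = beta1 * mb[ell] + (1 - beta1) * gradb[ell]
                vb[ell] = beta2 * vb[ell] + (1 - beta2) * gradb[ell] ** 2
                params.biases[ell] -= lr_t * mb[ell] / (np.sqrt(vb[ell]) + eps)

        loss = _full_loss(params, Z, W_loss, config.alpha)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch + 1}; try a lower learning rate"
            )
        loss_history.append(loss)
        p = config.patience
        if p > 0 and len(loss_history) >= 2 * p:
            prev = float(np.mean(loss_history[-2 * p : -p]))
            recent = float(np.mean(loss_history[-p:]))
            if prev - recent < config.tol * abs(prev):
                break

    return TrainResult(
        model=params,
        loss_history=loss_history,
        epochs_run=len(loss_history),
        spec=spec,
        config=config,
    )


def select_alpha(
    matrix,
    dropout_model,
    spec: NetworkSpec | None = None,
    config: TrainConfig | None = None,
    grid: list[float] = (1e-6, 1e-4, 1e-2),
    k: int = 5,
) -> float:
    """Pick the L2 rate alpha by k-fold cross-validation over cells.

    For each alpha the network is trained on k-1 folds and scored by the
    weighted reconstruction sum (no penalty) on the held-out cells; the alpha
    with the lowest mean held-out score wins, ties going to the larger alpha
    (the simpler model).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("alpha grid is empty")
    if any(a < 0 for a in grid):
        raise ValueError("alpha values must be >= 0")
    if k < 2:
        raise ValueError("k must be >= 2")
    Z, W_loss = _coerce_training_arrays(matrix, dropout_model)
    n_cells = Z.shape[0]
    if n_cells < k:
        raise ValueError(f"{n_cells} cells cannot be split into {k} folds")
    if config is None:
        config = TrainConfig()

    v = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, dtype=float)
    w = dropout_model.weight if isinstance(dropout_model, DropoutModel) else np.asarray(dropout_model)

    fold_rng = np.random.default_rng(config.seed)
    assignment = fold_rng.permutation(n_cells) % k

    scores = []
    for alpha in grid:
        fold_scores = []
        for fold in range(k):
            hold = assignment == fold
            res = train(
                v[:, ~hold],
                w[:, ~hold],
                spec=spec,
                config=replace(config, alpha=float(alpha)),
            )
            out = predict_log1p(res.model, Z[hold])
            fold_scores.append(float(np.sum(W_loss[hold] * (out - Z[hold]) ** 2)))
        scores.append(float(np.mean(fold_scores)))
    # lowest score wins; on a tie prefer the larger alpha
    best = min(zip(scores, [-a for a in grid]))
    return float(-best[1])
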