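"""End-to-end imputation: dropout fit -> autoencoder training -> prediction.

Two policies govern how the network's reconstruction becomes the output:

* ``zeros-only`` (default): observed nonzero entries pass through unchanged
  and only zeros — the dropout candidates — receive the prediction.
* ``denoise-all``: every entry is replaced by the reconstruction.

The loss anchors the reconstruction to well-observed entries (their dropout
probability is low, so their weight is high), which is what makes the
prediction at the zeroed positions an imputation rather than a smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import autoencoder, mmk_dropout
from .autoencoder import NetworkSpec, TrainConfig, TrainResult
from .data_model import ExpressionMatrix

__all__ = ["ImputationConfig", "impute", "NISCImputer"]

_POLICIES = ("zeros-only", "denoise-all")
_WEIGHTINGS = ("mmk", "uniform")


@dataclass
class ImputationConfig:
    """Settings for one imputation run.

    ``weighting="uniform"`` replaces the MM loss weights with all-ones,
    turning the objective into a plain log-space MSE — the ablation used to
    show the value of the weighted loss.
    """

    policy: str = "zeros-only"
    km_override: float | None = None
    train_config: TrainConfig = field(default_factory=TrainConfig)
    spec_overrides: dict | None = None
    weighting: str = "mmk"

    def __post_init__(self):
        if self.policy not in _POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}; choose from {_POLICIES}")
        if self.weighting not in _WEIGHTINGS:
            raise ValueError(f"unknown weighting {self.weighting!r}; choose from {_WEIGHTINGS}")


def _warn_if_normalized(values: np.ndarray) -> None:
    # RPKM/FPKM-scale data breaks the Michaelis-Menten dropout relationship
    nz = values[values > 0]
    if nz.size and np.mean(nz < 1) > 0.2:
        warnings.warn(
            "more than 20% of nonzero entries are below 1; this looks like "
            "RPKM/FPKM-normalized data, for which the Michaelis-Menten dropout "
            "model does not hold (counts and TPM are fine)",
            UserWarning,
        )


def impute(
    matrix: ExpressionMatrix,
    config: ImputationConfig | None = None,
) -> tuple[ExpressionMatrix, TrainResult]:
    """Impute a genes x cells matrix; returns (imputed matrix, training trace)."""
    if config is None:
        config = ImputationConfig()
    if not isinstance(matrix, ExpressionMatrix):
        matrix = ExpressionMatrix(np.asarray(matrix, dtype=float))
    if matrix.n_genes < 2 or matrix.n_cells < 2:
        raise ValueError("need at least 2 genes and 2 cells")
    _warn_if_normalized(matrix.values)

    dm = mmk_dropout.fit(matrix, km=config.km_override)
    weight = np.ones_like(dm.weight) if config.weighting == "uniform" else dm.weight

    spec = autoencoder.build_network(matrix.n_genes)
    if config.spec_overrides:
        spec = NetworkSpec(**{**spec.__dict__, **config.spec_overrides})
    result = autoencoder.train(matrix, weight, spec=spec, config=config.train_config)

    Z = np.log1p(matrix.values).T
    y_hat = np.expm1(autoencoder.predict_log1p(result.model, Z)).T
    y_hat[y_hat < 0] = 0.0

    if config.policy == "zeros-only":
        out = np.where(matrix.values > 0, matrix.values, y_hat)
    else:
        out = y_hat
    imputed = ExpressionMatrix(out, list(matrix.gene_ids), list(matrix.cell_ids))
    return imputed, result


class NISCImputer(TransformerMixin, BaseEstimator):
    """Autoencoder imputation of scRNA-seq dropouts, sklearn style.

    Follows the sklearn orientation (X is cells x genes, one row per cell);
    the module-level :func:`impute` handles the genes x cells
    :class:`~nisc.data_model.ExpressionMatrix` convention.

    Parameters
    ----------
    policy : {"zeros-only", "denoise-all"}
        Whether only zeros are replaced by the reconstruction, or all entries.
    km : float, optional
        Fix the Michaelis constant instead of estimating it from the data.
    alpha : float
        L2 regularization rate on the network's connection weights.
    hidden_dropout : float
        Dropout-regularization rate on hidden activations during training.
    weighting : {"mmk", "uniform"}
        Loss weighting; "uniform" is the plain log-MSE ablation.

    Attributes
    ----------
    km_ : float
        Michaelis constant used for the loss weights.
    model_ : MLPParams
        Trained network parameters.
    loss_history_ : list of float
        Full-data training loss per epoch.

    Examples
    --------
    >>> imp = NISCImputer(max_epochs=50, seed=0)
    >>> X_imputed = imp.fit_transform(X_raw)   # X_raw: cells x genes counts
    """

    def __init__(
        self,
        policy: str = "zeros-only",
        km: float | None = None,
        alpha: float = 1e-4,
        hidden_dropout: float = 0.2,
        learning_rate: float = 1e-3,
        max_epochs: int = 1000,
        batch_size: int = 64,
        patience: int = 100,
        tol: float = 1e-3,
        weighting: str = "mmk",
        seed: int = 0,
    ):
        self.policy = policy
        self.km = km
        self.alpha = alpha
        self.hidden_dropout = hidden_dropout
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.tol = tol
        self.weighting = weighting
        self.seed = seed

    def _config(self) -> ImputationConfig:
        return ImputationConfig(
            policy=self.policy,
            km_override=self.km,
            train_config=TrainConfig(
                alpha=self.alpha,
                learning_rate=self.learning_rate,
                max_epochs=self.max_epochs,
                batch_size=self.batch_size,
                patience=self.patience,
                tol=self.tol,
                seed=self.seed,
            ),
            spec_overrides={"dropout_rate": self.hidden_dropout},
            weighting=self.weighting,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("X must be 2-D with at least 2 cells and 2 genes")
        if np.any(X < 0) or not np.all(np.isfinite(X)):
            raise ValueError("X must be finite and non-negative")
        config = self._config()
        _warn_if_normalized(X)
        matrix = X.T  # genes x cells
        dm = mmk_dropout.fit(matrix, km=config.km_override)
        weight = np.ones_like(dm.weight) if config.weighting == "uniform" else dm.weight
        spec = autoencoder.build_network(matrix.shape[0], dropout_rate=self.hidden_dropout)
        result = autoencoder.train(matrix, weight, spec=spec, config=config.train_config)
        self.km_ = dm.km
        self.model_ = result.model
        self.loss_history_ = result.loss_history
        self.train_result_ = result
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"X has {X.shape[1]} genes, expected {self.n_features_in_}")
        y_hat = np.expm1(autoencoder.predict_log1p(self.model_, np.log1p(X)))
        y_hat[y_hat < 0] = 0.0
        if self.policy == "zeros-only":
            return np.where(X > 0, X, y_hat)
        return y_hat
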