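"""Michaelis-Menten dropout model.

In full-transcript scRNA-seq, dropout stems from the reverse-transcription
enzyme reaction, so the probability that a transcript with true expression
level S is lost follows Michaelis-Menten saturation:

    P(dropout | S) = 1 - S / (K_M + S)

K_M is the Michaelis constant: the expression level at which the dropout
probability is exactly one half. Applied entrywise to an observed matrix,
the complement 1 - P_ij serves as the per-entry weight of the reconstruction
loss — an observed zero gets weight exactly 0, a strongly expressed entry a
weight near 1.

K_M is fitted globally by least squares of each gene's observed zero fraction
against the MM curve evaluated at the gene's mean expression (zeros included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .data_model import ExpressionMatrix

__all__ = ["DropoutModel", "dropout_probability", "estimate_km", "fit", "MichaelisMentenDropout"]


def _values(matrix) -> np.ndarray:
    return matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, dtype=float)


def dropout_probability(s, km: float):
    """Dropout probability 1 - s/(km + s) for expression level(s) ``s``.

    Strictly decreasing in s, equal to 1 at s = 0 and 0.5 at s = km.
    """
    if km <= 0:
        raise ValueError(f"km must be positive, got {km}")
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("expression values must be non-negative")
    out = 1.0 - s / (km + s)
    return float(out) if out.ndim == 0 else out


def estimate_km(matrix) -> float:
    """Least-squares estimate of the Michaelis constant from a matrix.

    For each gene g let d_g be its observed zero fraction and m_g its mean
    expression over all cells (zeros included). Returns the km > 0 minimizing
    sum_g (d_g - km/(km + m_g))^2 by bounded 1-D optimization.

    A matrix with no zeros cannot constrain km; it yields the smallest
    representable positive km (all weights ~ 1) with a warning. An all-zero
    matrix raises.
    """
    v = _values(matrix)
    if v.size == 0:
        raise ValueError("empty matrix")
    if np.all(v == 0):
        raise ValueError("all-zero matrix: no expressed entries to fit km against")
    if not np.any(v == 0):
        warnings.warn(
            "matrix has no zero entries; km set to the smallest positive float "
            "(all loss weights ~ 1)",
            UserWarning,
        )
        return float(np.finfo(float).tiny)
    d = np.mean(v == 0, axis=1)  # per-gene zero fraction
    m = v.mean(axis=1)  # per-gene mean, zeros included
    lo = 1e-12
    hi = float(m.max()) * 1e3

    def sse(km):
        return float(np.sum((d - km / (km + m)) ** 2))

    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
    return float(max(res.x, lo))


@dataclass
class DropoutModel:
    """Fitted Michaelis constant with per-entry dropout probabilities.

    Attributes
    ----------
    km : float
        Michaelis constant, same units as the expression values.
    prob : ndarray
        Dropout probabilities, 1 exactly where the observation is 0.
    weight : ndarray
        Loss weights 1 - prob, 0 exactly where the observation is 0.
    """

    km: float
    prob: np.ndarray
    weight: np.ndarray


def fit(matrix, km: float | None = None) -> DropoutModel:
    """Fit the entrywise dropout model, estimating km unless supplied."""
    v = _values(matrix)
    if km is None:
        km = estimate_km(matrix)
    if km <= 0:
        raise ValueError(f"km must be positive, got {km}")
    prob = dropout_probability(v, km)
    # exactness at zeros matters: it is what keeps log of zero out of the loss
    prob = np.where(v == 0, 1.0, prob)
    weight = np.where(v == 0, 0.0, 1.0 - prob)
    return DropoutModel(km=float(km), prob=prob, weight=weight)


class MichaelisMentenDropout(BaseEstimator):
    """Estimator wrapper around the MM dropout fit.

    Follows the sklearn orientation: X has shape (n_cells, n_genes), i.e.
    cells are samples. Fitting estimates ``km_``; ``weights(X)`` returns the
    per-entry loss weights for any matrix on the same scale.

    Parameters
    ----------
    km : float, optional
        Fix the Michaelis constant instead of estimating it.
    """

    def __init__(self, km: float | None = None):
        self.km = km

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.km is not None:
            if self.km <= 0:
                raise ValueError(f"km must be positive, got {self.km}")
            self.km_ = float(self.km)
        else:
            self.km_ = estimate_km(X.T)  # estimator X is cells x genes
        self.n_features_in_ = X.shape[1]
        return self

    def probability(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.where(X == 0, 1.0, dropout_probability(X, self.km_))

    def weights(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.where(X == 0, 0.0, 1.0 - self.probability(X))
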