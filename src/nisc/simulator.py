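"""Group-structured scRNA-seq count simulation with calibrated dropout.

The generative model is a gamma-Poisson hierarchy in the Splatter mould:

1. per-gene base mean  mu_g ~ Gamma(mean_shape, rate=mean_rate)
2. a marker mask: each gene is differentially expressed with probability
   ``de_prob``; each group draws an independent lognormal fold factor for
   every marker gene (non-markers keep factor 1)
3. cells assigned to groups uniformly; library sizes
   L_j ~ LogNormal(lib_logmean, lib_logsd)
4. expected expression lambda_ij = L_j * mu_g f_{g,k(j)} / sum_g' mu_g' f_{g',k(j)}
5. truth counts ~ Poisson(lambda), or gamma-Poisson when dispersion > 0
6. dropout corruption: each positive entry is kept with the Michaelis-Menten
   keep-probability t/(km + t); km is found by bisection so the expected zero
   fraction of the corrupted matrix hits ``target_sparsity``.

Because the corruption uses the same saturation law the imputer's loss
assumes, the simulator probes the method under a correctly specified dropout
model; a logistic option exists for misspecification experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ExpressionMatrix

__all__ = ["SimConfig", "SimResult", "simulate", "calibrate_sparsity", "mask_to_sparsity"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; defaults give a desk-scale two-condition design.

    ``de_prob`` is the differential rate: the expected fraction of genes that
    are cell-type markers. ``target_sparsity`` triggers dropout calibration;
    without it (and without ``dropout_km``) the raw matrix equals the truth.
    """

    n_genes: int = 800
    n_cells: int = 1000
    n_groups: int = 4
    de_prob: float = 0.2
    de_factor_logmean: float = 0.3
    de_factor_logsd: float = 0.4
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_logmean: float = 9.0
    lib_logsd: float = 0.25
    dispersion: float = 0.0
    target_sparsity: float | None = None
    dropout_km: float | None = None
    dropout_shape: str = "mm"
    seed: int = 0

    def __post_init__(self):
        if self.n_groups > self.n_cells:
            raise ValueError("n_groups cannot exceed n_cells")
        if not 0 <= self.de_prob <= 1:
            raise ValueError("de_prob must be in [0, 1]")
        if self.target_sparsity is not None and not 0 < self.target_sparsity < 1:
            raise ValueError("target_sparsity must be in (0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.dropout_shape not in ("mm", "logistic"):
            raise ValueError("dropout_shape must be 'mm' or 'logistic'")


@dataclass
class SimResult:
    """Paired truth/raw matrices with group labels and the marker mask."""

    truth: ExpressionMatrix
    raw: ExpressionMatrix
    labels: np.ndarray
    marker_mask: np.ndarray
    km_used: float
    config: SimConfig


def expected_sparsity(truth_values: np.ndarray, km: float) -> float:
    """Expected zero fraction after MM dropout with constant km.

    A positive entry t survives with probability t/(km + t); existing zeros
    stay zero. The expectation is deterministic given the truth matrix.
    """
    t = np.asarray(truth_values, dtype=float)
    p_zero = np.where(t > 0, km / (km + t), 1.0)
    return float(p_zero.mean())


def calibrate_sparsity(truth, target: float) -> float:
    """Bisection for the km whose expected post-dropout sparsity hits target.

    Raises when the target is below the truth's own zero fraction (dropout
    can only add zeros) or above what the search interval can reach.
    """
    t = truth.values if isinstance(truth, ExpressionMatrix) else np.asarray(truth, dtype=float)
    lo, hi = 1e-6, float(t.max()) * 10.0
    f_lo, f_hi = expected_sparsity(t, lo), expected_sparsity(t, hi)
    if target < f_lo:
        raise ValueError(
            f"target sparsity {target:.4f} is below the feasible minimum {f_lo:.4f} "
            "(the truth matrix's own zero fraction)"
        )
    if target > f_hi:
        raise ValueError(
            f"target sparsity {target:.4f} exceeds the feasible maximum {f_hi:.4f} "
            "for this truth matrix"
        )
    for _ in range(200):
        mid = np.sqrt(lo * hi)  # km spans orders of magnitude; bisect in log
        f_mid = expected_sparsity(t, mid)
        if abs(f_mid - target) <= 0.005:
            return float(mid)
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _apply_dropout(truth: np.ndarray, km: float, shape: str, rng: np.random.Generator):
    if shape == "mm":
        keep_p = np.where(truth > 0, truth / (km + truth), 0.0)
    else:  # logistic in log-expression, midpoint at log(km)
        with np.errstate(divide="ignore"):
            x = np.where(truth > 0, np.log(np.maximum(truth, 1e-300)), -np.inf)
        keep_p = np.where(truth > 0, 1.0 / (1.0 + np.exp(-(x - np.log(km)))), 0.0)
    keep = rng.random(truth.shape) < keep_p
    return truth * keep


def simulate(config: SimConfig | None = None, **kwargs) -> SimResult:
    """Draw one paired (truth, raw, labels) dataset from the model above."""
    if config is None:
        config = SimConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a SimConfig or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    G, N, K = config.n_genes, config.n_cells, config.n_groups

    mu = rng.gamma(config.mean_shape, 1.0 / config.mean_rate, size=G)
    marker_mask = rng.random(G) < config.de_prob
    factors = np.ones((G, K))
    n_markers = int(marker_mask.sum())
    if n_markers:
        factors[marker_mask, :] = rng.lognormal(
            config.de_factor_logmean, config.de_factor_logsd, size=(n_markers, K)
        )

    labels = rng.integers(0, K, size=N)
    lib = rng.lognormal(config.lib_logmean, config.lib_logsd, size=N)

    profile = mu[:, None] * factors  # (G, K) unnormalized group profiles
    profile = profile / profile.sum(axis=0, keepdims=True)
    lam = profile[:, labels] * lib[None, :]

    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, lam * config.dispersion)
    truth_values = rng.poisson(lam).astype(float)

    km = 0.0
    raw_values = truth_values
    if config.target_sparsity is not None:
        km = calibrate_sparsity(truth_values, config.target_sparsity)
    elif config.dropout_km is not None:
        km = float(config.dropout_km)
    if km > 0:
        raw_values = _apply_dropout(truth_values, km, config.dropout_shape, rng)

    gene_ids = [f"gene{i + 1}" for i in range(G)]
    cell_ids = [f"cell{j + 1}" for j in range(N)]
    return SimResult(
        truth=ExpressionMatrix(truth_values, gene_ids, cell_ids),
        raw=ExpressionMatrix(raw_values.copy(), list(gene_ids), list(cell_ids)),
        labels=labels,
        marker_mask=marker_mask,
        km_used=km,
        config=config,
    )


def mask_to_sparsity(matrix: ExpressionMatrix, target: float, seed: int = 0) -> ExpressionMatrix:
    """Zero out uniformly chosen nonzero entries until the zero count reaches
    round(target * m * n). The standard way to turn a dense, low-noise real
    dataset into a ground-truthed imputation benchmark.
    """
    if not 0 <= target <= 1:
        raise ValueError("target must be in [0, 1]")
    v = matrix.values.copy()
    total = v.size
    n_zero = int(np.count_nonzero(v == 0))
    wanted = int(round(target * total))
    if wanted < n_zero:
        raise ValueError(
            f"target sparsity {target:.4f} is below the current sparsity {n_zero / total:.4f}"
        )
    extra = wanted - n_zero
    if extra:
        nz_flat = np.flatnonzero(v)
        rng = np.random.default_rng(seed)
        chosen = rng.choice(nz_flat, size=extra, replace=False)
        v.flat[chosen] = 0.0
    return ExpressionMatrix(v, list(matrix.gene_ids), list(matrix.cell_ids))
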