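"""Approximate Bayesian Computation for the time to fixation.

The target variable is log10(tf).  Each query's posterior is formed by
accepting the ``ceil(tolerance * N)`` training simulations nearest in
(scaled) summary-statistic space, optionally followed by Beaumont-style
regression adjustment: a local-linear (or ridge) regression of the target on
the statistics over the accepted points, weighted by an Epanechnikov kernel
on distance, with adjusted draws theta_i* = theta_i - (S_i - s_query)' beta.

Statistics are made commensurable by dividing each by its median absolute
deviation over the training set (falling back to the standard deviation when
the MAD is zero, dropping the statistic when both are zero), after the same
log10 transforms used by the regression model of the study (pi, Watterson's
theta and Kim's omega enter on the log10 scale).

The study grid crosses 3 methods x 7 tolerances x 3 point estimates = 63
configurations, scored by the Pearson correlation between validation
predictions and true log10(tf).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import STAT_NAMES

__all__ = [
    "ABCConfig",
    "Posterior",
    "default_grid",
    "transform_stats",
    "normalize_stats",
    "abc_rejection",
    "regression_adjust",
    "point_estimate",
    "predict",
    "predict_batch",
    "grid_search",
    "random_search_coverage",
]

METHODS = ("rejection", "loclinear", "ridge")
TOLERANCES = (0.025, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3)
ESTIMATES = ("mean", "median", "mode")

LOG_STATS = ("pi", "thetaW", "omega")


@dataclass(frozen=True)
class ABCConfig:
    method: str = "rejection"
    tolerance: float = 0.1
    estimate: str = "mean"

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown ABC method {self.method!r}")
        if not 0 < self.tolerance <= 1:
            raise ValueError("tolerance must be in (0, 1]")
        if self.estimate not in ESTIMATES:
            raise ValueError(f"unknown point estimate {self.estimate!r}")


@dataclass
class Posterior:
    """Accepted (possibly regression-adjusted) target values with weights."""

    values: np.ndarray
    weights: np.ndarray  # nonnegative, summing to 1


def default_grid() -> list[ABCConfig]:
    """The study's 63-configuration grid (3 methods x 7 tolerances x 3
    estimates)."""
    return [
        ABCConfig(method=m, tolerance=t, estimate=e)
        for m, t, e in product(METHODS, TOLERANCES, ESTIMATES)
    ]


def random_search_coverage(top_fraction: float = 0.05, draws: int = 60) -> float:
    """Probability that `draws` independent uniform configurations include at
    least one in the top `top_fraction` of the performance range:
    1 - (1 - top_fraction)^draws."""
    return 1.0 - (1.0 - top_fraction) ** draws


def transform_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the model-scale transforms: log10 on pi, thetaW and omega."""
    out = table.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        for name in LOG_STATS:
            if name in out.columns:
                out[name] = np.log10(out[name].to_numpy(dtype=float))
    return out


def normalize_stats(
    train_stats: np.ndarray, query_stats: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale each statistic by its training-set median absolute deviation.

    Returns (scaled_train, scaled_query, kept_column_mask).  Columns whose
    MAD and standard deviation are both zero carry no distance information
    and are dropped with a warning.
    """
    train_stats = np.asarray(train_stats, dtype=float)
    query_stats = np.atleast_2d(np.asarray(query_stats, dtype=float))
    scale = sps.median_abs_deviation(train_stats, axis=0)
    sd = train_stats.std(axis=0)
    scale = np.where(scale > 0, scale, sd)
    kept = scale > 0
    if not kept.all():
        warnings.warn(
            f"{(~kept).sum()} constant statistic(s) excluded from the ABC distance",
            stacklevel=2,
        )
    return (
        train_stats[:, kept] / scale[kept],
        query_stats[:, kept] / scale[kept],
        kept,
    )


def _n_accept(tolerance: float, n_train: int) -> int:
    return min(n_train, math.ceil(tolerance * n_train))


def abc_rejection(
    query: np.ndarray,
    train: np.ndarray,
    targets: np.ndarray,
    tolerance: float,
) -> tuple[Posterior, np.ndarray, np.ndarray]:
    """Accept the ceil(tolerance*N) nearest training records by Euclidean
    distance in scaled statistic space; uniform weights.

    Returns (posterior, accepted_indices, accepted_distances).
    """
    d = np.sqrt(((train - query) ** 2).sum(axis=1))
    k = _n_accept(tolerance, len(train))
    idx = np.argpartition(d, k - 1)[:k]
    idx = idx[np.argsort(d[idx], kind="stable")]
    post = Posterior(values=targets[idx].astype(float), weights=np.full(k, 1.0 / k))
    return post, idx, d[idx]


def _epanechnikov(dist: np.ndarray) -> np.ndarray:
    dmax = dist.max()
    if dmax == 0:
        return np.ones_like(dist)
    u = dist / dmax
    return 1.0 - u**2


def regression_adjust(
    posterior: Posterior,
    accepted_stats: np.ndarray,
    accepted_dist: np.ndarray,
    query: np.ndarray,
    method: str = "loclinear",
    ridge_lambda: float = 1e-3,
) -> Posterior:
    """Beaumont-style local regression correction of the accepted draws.

    Fits a distance-kernel-weighted linear (or ridge) regression of the
    target on the centered statistics X_i = S_i - s_query and returns the
    adjusted values theta_i* = theta_i - X_i' beta with the kernel weights
    carried into the posterior.  A singular local-linear design falls back
    to ridge with a warning.
    """
    if method not in ("loclinear", "ridge"):
        raise ValueError(f"unknown adjustment method {method!r}")
    theta = posterior.values
    X = accepted_stats - query.reshape(1, -1)
    kw = _epanechnikov(accepted_dist)
    kw = np.maximum(kw, 1e-12)
    Xd = np.column_stack([np.ones(len(X)), X])
    sw = np.sqrt(kw)
    A = Xd * sw[:, None]
    b = theta * sw

    def _solve_ridge(lam: float) -> np.ndarray:
        P = A.T @ A
        P[1:, 1:] += lam * np.eye(X.shape[1])  # intercept unpenalized
        return np.linalg.solve(P, A.T @ b)

    if method == "loclinear":
        P = A.T @ A
        if np.linalg.matrix_rank(P) < P.shape[0]:
            warnings.warn(
                "singular local-linear design; falling back to ridge",
                stacklevel=2,
            )
            coef = _solve_ridge(ridge_lambda)
        else:
            coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    else:
        coef = _solve_ridge(ridge_lambda)

    beta = coef[1:]
    adjusted = theta - X @ beta
    w = kw / kw.sum()
    return Posterior(values=adjusted, weights=w)


def point_estimate(posterior: Posterior, estimate: str = "mean") -> float:
    """Weighted mean / weighted median / KDE mode of the posterior values."""
    v = posterior.values
    w = posterior.weights
    if estimate == "mean":
        return float(np.sum(v * w))
    if estimate == "median":
        order = np.argsort(v)
        cw = np.cumsum(w[order])
        return float(v[order][np.searchsorted(cw, 0.5 * cw[-1])])
    if estimate == "mode":
        if np.ptp(v) == 0:
            return float(v[0])
        kde = sps.gaussian_kde(v, bw_method="silverman", weights=w)
        grid = np.linspace(v.min(), v.max(), 512)
        return float(grid[np.argmax(kde(grid))])
    raise ValueError(f"unknown point estimate {estimate!r}")


def predict(
    query: np.ndarray,
    train: np.ndarray,
    targets: np.ndarray,
    config: ABCConfig,
    ridge_lambda: float = 1e-3,
) -> float:
    """One query's ABC point prediction (inputs already scaled)."""
    post, idx, dist = abc_rejection(query, train, targets, config.tolerance)
    if config.method != "rejection":
        post = regression_adjust(
            post, train[idx], dist, query, config.method, ridge_lambda
        )
    return point_estimate(post, config.estimate)


def predict_batch(
    queries: np.ndarray,
    train: np.ndarray,
    targets: np.ndarray,
    config: ABCConfig,
    ridge_lambda: float = 1e-3,
) -> np.ndarray:
    """ABC point predictions for each row of `queries` (scaled space)."""
    return np.array([
        predict(q, train, targets, config, ridge_lambda) for q in queries
    ])


def grid_search(
    train_stats: np.ndarray,
    train_targets: np.ndarray,
    val_stats: np.ndarray,
    val_targets: np.ndarray,
    grid: Optional[Sequence[ABCConfig]] = None,
    ridge_lambda: float = 1e-3,
) -> tuple[ABCConfig, pd.DataFrame]:
    """Score every configuration by the Pearson correlation between its
    validation predictions and the true targets; return the argmax and the
    full score table.

    Inputs are raw (untransformed) statistic matrices in STAT_NAMES column
    order, or any consistent column order; scaling is fit on the training
    set.  Ties break toward smaller tolerance, then toward the method order
    rejection < loclinear < ridge, then mean < median < mode.
    """
    if grid is None:
        grid = default_grid()
    tr, va, _ = normalize_stats(train_stats, val_stats)
    rows = []
    best_key = None
    best_config = None
    for config in grid:
        preds = predict_batch(va, tr, train_targets, config, ridge_lambda)
        if np.ptp(preds) == 0 or not np.all(np.isfinite(preds)):
            score = -np.inf
        else:
            score = float(sps.pearsonr(preds, val_targets)[0])
            if not np.isfinite(score):
                score = -np.inf
        rows.append({
            "method": config.method, "tolerance": config.tolerance,
            "estimate": config.estimate, "pearson_r": score,
        })
        key = (
            -score, config.tolerance, METHODS.index(config.method),
            ESTIMATES.index(config.estimate),
        )
        if best_key is None or key < best_key:
            best_key = key
            best_config = config
    return best_config, pd.DataFrame(rows)


def stats_matrix(table: pd.DataFrame, names: Sequence[str] = STAT_NAMES) -> np.ndarray:
    """Model-scale statistic matrix (log transforms applied) from a
    statistics table."""
    return transform_stats(table)[list(names)].to_numpy(dtype=float)
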