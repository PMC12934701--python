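"""Dataset stratification, splitting, partial-R2 analysis, and model
comparison.

Completed simulations are downsampled to a uniform distribution of
log10(tf): the histogram over 0.1-wide bins is flattened by sampling every
occupied bin, without replacement, down to the smallest bin's count.  The
retained ids are then split 80/10/10 into training/validation/test sets.

The partial R2 of each statistic quantifies the extra variation in
log10(tf + ta) it explains beyond the other 16: with SSE(m) the error sum of
squares of the ordinary-least-squares model that drops the statistic and
SSE(M) that of the full 17-term model,

    R2_m = (SSE(m) - SSE(M)) / SSE(m).

Model comparisons report the Pearson correlation between predicted and true
log10(tf) with a Fisher-z 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .abc import transform_stats
from .sumstats import STAT_NAMES

__all__ = [
    "DatasetSplit",
    "PartialR2Result",
    "ModelReport",
    "stratify_uniform",
    "split_dataset",
    "partial_r2",
    "pearson_ci",
    "benchmark_report",
]

BIN_WIDTH = 0.1


@dataclass
class DatasetSplit:
    train: list
    validation: list
    test: list

    def __post_init__(self):
        sets = [set(self.train), set(self.validation), set(self.test)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("split sets must be disjoint")


@dataclass
class PartialR2Result:
    partial_r2: pd.Series  # indexed by statistic name
    sse_full: float
    sse_reduced: pd.Series
    n: int
    rank_deficient: list


@dataclass
class ModelReport:
    model: str
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def stratify_uniform(
    manifest: pd.DataFrame,
    rng: np.random.Generator,
    bin_width: float = BIN_WIDTH,
    min_bin_fraction: float = 0.0,
) -> list:
    """Downsample completed simulations to a uniform log10(tf) histogram.

    Bins of width `bin_width` partition log10(tf); every occupied bin is
    randomly downsampled without replacement to the minimum occupied-bin
    count.  Returns the retained sim_id list (sorted for determinism).

    Because tf is continuous, the extreme bins of any finite sample hold a
    handful of records and would drag every bin down with them; a study
    therefore equalizes over a dense tf span.  `min_bin_fraction` drops
    bins holding fewer than that fraction of the median occupied-bin count
    before equalizing (0 applies the bare rule to every occupied bin).
    """
    ok = manifest[(manifest["status"] == "complete") & manifest["tf"].notna()]
    if len(ok) == 0:
        return []
    logtf = np.log10(ok["tf"].to_numpy(dtype=float))
    bins = np.floor(logtf / bin_width).astype(int)
    ids = ok["sim_id"].to_numpy()
    counts = pd.Series(bins).value_counts()
    if min_bin_fraction > 0:
        counts = counts[counts >= min_bin_fraction * counts.median()]
        if len(counts) == 0:
            return []
    m = int(counts.min())
    keep = []
    for b in sorted(counts.index):
        members = ids[bins == b]
        members = np.sort(members)
        chosen = rng.choice(members, size=m, replace=False)
        keep.extend(chosen.tolist())
    return sorted(keep)


def split_dataset(
    ids: Sequence,
    rng: np.random.Generator,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> DatasetSplit:
    """Random train/validation/test partition.  Validation and test sizes
    are floored; the remainder goes to training."""
    ids = list(ids)
    if len(ids) < 10:
        raise ValueError("need at least 10 ids to split")
    perm = rng.permutation(len(ids))
    n_val = int(np.floor(fractions[1] * len(ids)))
    n_test = int(np.floor(fractions[2] * len(ids)))
    val_idx = perm[:n_val]
    test_idx = perm[n_val : n_val + n_test]
    train_idx = perm[n_val + n_test :]
    return DatasetSplit(
        train=[ids[i] for i in train_idx],
        validation=[ids[i] for i in val_idx],
        test=[ids[i] for i in test_idx],
    )


def _model_frame(stats_table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix (model-scale transforms applied) and response
    log10(tf + ta), restricted to rows where both are finite."""
    t = transform_stats(stats_table)
    y = np.log10(
        stats_table["tf"].to_numpy(dtype=float)
        + stats_table["ta"].to_numpy(dtype=float)
    )
    X = t[STAT_NAMES].to_numpy(dtype=float)
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    return t.loc[ok, STAT_NAMES], y[ok]


def partial_r2(stats_table: pd.DataFrame) -> PartialR2Result:
    """Partial R2 of each of the 17 statistics for log10(tf + ta).

    `stats_table` must carry the 17 statistic columns (raw scale) plus `tf`
    and `ta`.  Records where any log-transformed term or the response is
    undefined are dropped.  Statistics whose reduced fit is rank-deficient
    are flagged.
    """
    X, y = _model_frame(stats_table)
    n = len(y)
    Xf = sm.add_constant(X.to_numpy(), has_constant="add")
    full = sm.OLS(y, Xf).fit()
    sse_full = float(np.sum(full.resid**2))
    rank_full = np.linalg.matrix_rank(Xf)
    out = {}
    sse_red = {}
    flagged = []
    for j, name in enumerate(STAT_NAMES):
        Xr = np.delete(X.to_numpy(), j, axis=1)
        Xr = sm.add_constant(Xr, has_constant="add")
        red = sm.OLS(y, Xr).fit()
        sse_m = float(np.sum(red.resid**2))
        out[name] = (sse_m - sse_full) / sse_m if sse_m > 0 else np.nan
        sse_red[name] = sse_m
        if np.linalg.matrix_rank(Xr) < Xr.shape[1] or rank_full < Xf.shape[1]:
            flagged.append(name)
    return PartialR2Result(
        partial_r2=pd.Series(out),
        sse_full=sse_full,
        sse_reduced=pd.Series(sse_red),
        n=n,
        rank_deficient=flagged,
    )


def pearson_ci(
    predictions: np.ndarray,
    truths: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float], float, int]:
    """Pearson r with Fisher-z confidence interval and two-sided p-value."""
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    n = len(predictions)
    if n < 4:
        raise ValueError("need at least 4 points")
    if np.std(predictions) == 0 or np.std(truths) == 0:
        return np.nan, (np.nan, np.nan), np.nan, n
    r, p = sps.pearsonr(predictions, truths)
    z = np.arctanh(r)
    zcrit = sps.norm.ppf(1 - alpha / 2)
    half = zcrit / np.sqrt(n - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return float(r), ci, float(p), n


def benchmark_report(
    predictions: dict[str, pd.DataFrame],
    ta_threshold: float = 1000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Head-to-head comparison of model prediction tables.

    Each table must have columns (sim_id, truth, prediction) on the log10
    scale, plus optionally `ta`; all models must cover the identical test
    set.  Returns (report, errors) where `report` has one row per model
    (r, CI, p, n, CI-overlap flag vs the best model) and `errors`
    stratifies mean absolute error by old (ta > threshold) vs young sweeps.
    """
    keys = None
    for name, tab in predictions.items():
        k = tuple(sorted(tab["sim_id"].astype(str)))
        if keys is None:
            keys = k
        elif k != keys:
            raise ValueError(f"model {name!r} scored a different test set")
    rows = []
    for name, tab in predictions.items():
        truth = tab["truth"].to_numpy(dtype=float)
        pred = tab["prediction"].to_numpy(dtype=float)
        if len(tab) < 4 or np.std(pred) == 0:
            flag = "constant predictions" if len(tab) >= 4 else "too few records"
            rows.append({"model": name, "r": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "n": len(tab),
                         "flag": flag})
            continue
        r, ci, p, n = pearson_ci(pred, truth)
        rows.append({"model": name, "r": r, "ci_low": ci[0], "ci_high": ci[1],
                     "p": p, "n": n, "flag": ""})
    report = pd.DataFrame(rows)
    finite = report[report["r"].notna()]
    if len(finite) > 1:
        best = finite.loc[finite["r"].idxmax()]
        overlap = (report["ci_low"] <= best["ci_high"]) & (
            report["ci_high"] >= best["ci_low"]
        )
        report["ci_overlaps_best"] = overlap
    err_rows = []
    for name, tab in predictions.items():
        if "ta" not in tab.columns:
            continue
        ae = np.abs(tab["prediction"] - tab["truth"])
        old = tab["ta"] > ta_threshold
        err_rows.append({
            "model": name,
            "mae_old": float(ae[old].mean()) if old.any() else np.nan,
            "mae_young": float(ae[~old].mean()) if (~old).any() else np.nan,
            "n_old": int(old.sum()), "n_young": int((~old).sum()),
        })
    return report, pd.DataFrame(err_rows)
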