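"""Decoding-quality metrics: per-dimension R^2, one-way ANOVA, degradation curves.

R^2 here is the coefficient of determination
``1 - <(x - xhat)^2> / <(x - <x>)^2>`` between decoded and actual
trajectories, computed per kinematic dimension.  Unlike the squared
correlation, this definition is negative whenever the predictor does
worse than the observed mean, and it is reported as-is by default (an
optional clamp to [0, 1] is available for comparison with conventions
that assume a non-negative range).

Group comparisons across loss conditions use a classical one-way ANOVA.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import STATE_LABELS

__all__ = [
    "r_squared",
    "r2_by_dimension",
    "anova_oneway",
    "R2_COLUMNS",
    "make_r2_table",
    "degradation_curves",
    "cross_model_table",
]

#: schema of the tidy R^2 table produced by the experiment layer
R2_COLUMNS = ["model", "loss_rate", "replicate", "seed", "achieved_rate"] + [
    f"r2_{d}" for d in STATE_LABELS]


def r_squared(x: np.ndarray, x_hat: np.ndarray, clip: bool = False) -> float:
    """Coefficient of determination between observed ``x`` and predicted ``x_hat``.

    ``R^2 = 1 - mean((x - x_hat)^2) / mean((x - mean(x))^2)``.  Can be
    negative for predictors worse than the mean; ``clip=True`` clamps the
    result into [0, 1].

    Raises
    ------
    ValueError
        On length mismatch, fewer than 2 samples, or zero variance in x.
    """
    x = np.asarray(x, dtype=float).ravel()
    x_hat = np.asarray(x_hat, dtype=float).ravel()
    if x.size != x_hat.size:
        raise ValueError("x and x_hat must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    var = np.mean((x - x.mean()) ** 2)
    if var == 0:
        raise ValueError("x has zero variance; R^2 undefined")
    r2 = 1.0 - np.mean((x - x_hat) ** 2) / var
    return float(np.clip(r2, 0.0, 1.0)) if clip else float(r2)


def r2_by_dimension(actual: np.ndarray, predicted: np.ndarray,
                    clip: bool = False) -> np.ndarray:
    """Column-wise :func:`r_squared` over an N x 6 state matrix pair."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must share a shape")
    return np.array([r_squared(actual[:, d], predicted[:, d], clip=clip)
                     for d in range(actual.shape[1])])


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA over ``k >= 2`` groups of values.

    Returns the F statistic (between/within mean square, df ``(k-1, n-k)``)
    and its p-value from the F distribution.

    Raises
    ------
    ValueError
        With fewer than two groups, any group smaller than 2, or when all
        values are identical (F undefined).
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical; F statistic undefined")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def make_r2_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble tidy replicate rows into the canonical R^2 table."""
    table = pd.DataFrame(list(rows))
    missing = [c for c in R2_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"rows missing columns: {missing}")
    return table[R2_COLUMNS]


def degradation_curves(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of R^2 over replicates, per model x loss rate x dimension.

    Input is the tidy R^2 table (see ``R2_COLUMNS``); output is long-form
    with columns (model, loss_rate, dimension, mean, sd, n).  ``sd`` is the
    sample standard deviation, 0 for a single replicate.
    """
    if len(table) == 0:
        raise ValueError("empty R^2 table")
    value_cols = [f"r2_{d}" for d in STATE_LABELS]
    long = table.melt(id_vars=["model", "loss_rate"], value_vars=value_cols,
                      var_name="dimension", value_name="r2")
    long["dimension"] = long["dimension"].str.removeprefix("r2_")
    curves = (long.groupby(["model", "loss_rate", "dimension"], sort=True)["r2"]
              .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
              .reset_index())
    curves["sd"] = curves["sd"].fillna(0.0)
    return curves


def cross_model_table(curves: pd.DataFrame, dimension: str) -> pd.DataFrame:
    """Per-dimension cross-model comparison: loss rate x model mean-R^2 grid."""
    if dimension not in STATE_LABELS:
        raise ValueError(f"dimension must be one of {STATE_LABELS}")
    sub = curves[curves["dimension"] == dimension]
    return sub.pivot(index="loss_rate", columns="model", values="mean")
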