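"""Matplotlib figures mirroring the analysis outputs: loss-rate traces,
degradation curves, and reach reconstructions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .loss import LossReport, loss_rate_series
from .synthetic import STATE_LABELS

__all__ = ["plot_loss_rate_series", "plot_degradation_curves",
           "plot_reconstruction"]


def plot_loss_rate_series(reports: dict[str, LossReport],
                          bin_width_s: float = 0.128):
    """Per-bin loss rate over time for several models, one colour each."""
    fig, ax = plt.subplots(figsize=(9, 3.2))
    for name, rep in reports.items():
        r = loss_rate_series(rep)
        t = np.arange(r.size) * bin_width_s
        ax.plot(t, 100 * r, lw=0.8, label=name, alpha=0.85)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("packet loss rate (%)")
    ax.legend(frameon=False, ncols=len(reports))
    fig.tight_layout()
    return fig


def plot_degradation_curves(curves: pd.DataFrame, by: str = "model"):
    """R^2 vs loss rate, one panel per kinematic dimension.

    ``by='model'`` overlays models within each panel (the cross-model
    comparison view); shaded bands are +/- 1 sd over replicates.
    """
    fig, axes = plt.subplots(2, 3, figsize=(11, 6), sharex=True)
    for ax, dim in zip(axes.ravel(), STATE_LABELS):
        sub = curves[curves["dimension"] == dim]
        for key, grp in sub.groupby(by):
            grp = grp.sort_values("loss_rate")
            ax.plot(100 * grp["loss_rate"], grp["mean"], marker="o",
                    ms=3, label=str(key))
            ax.fill_between(100 * grp["loss_rate"], grp["mean"] - grp["sd"],
                            grp["mean"] + grp["sd"], alpha=0.2)
        ax.set_title(dim)
    for ax in axes[1]:
        ax.set_xlabel("packet loss rate (%)")
    for ax in axes[:, 0]:
        ax.set_ylabel(r"$R^2$")
    axes[0, 0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def plot_reconstruction(trace: pd.DataFrame, label: str = ""):
    """Actual vs decoded time series for one kinematic dimension."""
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(trace["time"], trace["actual"], "k--", lw=1, label="actual")
    ax.plot(trace["time"], trace["predicted"], lw=1, label=f"decoded {label}".strip())
    ax.set_xlabel("time (s)")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig
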