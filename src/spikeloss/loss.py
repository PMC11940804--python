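"""Packet-loss injection models for binned spike-count matrices.

Four corruption mechanisms seen in wireless neural-signal transmission,
each a transform ``CountMatrix -> (corrupted CountMatrix, LossReport)``:

congestion
    Per-bin traffic cap: when the total spike count of a bin exceeds the
    bandwidth ``Z`` packets, only the ``Z`` earliest spikes (within-bin
    arrival order) survive.
single
    Distributed loss of individual spike events: ``L`` decrements of
    random positive matrix entries.
full
    Distributed loss of whole bins: ``L = round(p*N)`` rows zeroed.
burst
    Gilbert-Elliott two-state (Good/Bad) Markov channel: bins visited in
    the Bad state lose a configurable fraction of their spikes (all of
    them by default), producing temporally clustered loss.

Every model conserves accounting: sum(original) - sum(lost) equals the
corrupted total, and every stochastic model is reproducible under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .ingest import CountMatrix, SpikeEvents

__all__ = [
    "LossReport",
    "GEParams",
    "CongestionParams",
    "DistributedParams",
    "congestion_loss",
    "full_loss",
    "single_loss",
    "burst_loss",
    "ge_params_from",
    "calibrate_bandwidth",
    "loss_rate_series",
]


def _round_half_away(x: float) -> int:
    """Round half away from zero (3.5 -> 4), unlike banker's rounding."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class LossReport:
    """Per-bin accounting of a loss-model application.

    ``lost_per_bin`` and ``original_per_bin`` count spikes (packets);
    ``mask`` flags bins hit at the bin level (full/burst models; all-False
    for spike-level models).  ``overall_rate`` is total lost / total
    original.
    """

    lost_per_bin: np.ndarray
    original_per_bin: np.ndarray
    mask: np.ndarray
    model_name: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lost_per_bin = np.asarray(self.lost_per_bin, dtype=np.int64)
        self.original_per_bin = np.asarray(self.original_per_bin, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.lost_per_bin.shape == self.original_per_bin.shape == self.mask.shape):
            raise ValueError("per-bin vectors must share one shape")
        if np.any(self.lost_per_bin < 0) or np.any(self.lost_per_bin > self.original_per_bin):
            raise ValueError("need 0 <= lost_per_bin <= original_per_bin")

    @property
    def overall_rate(self) -> float:
        total = self.original_per_bin.sum()
        return float(self.lost_per_bin.sum() / total) if total > 0 else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-bin table: bin, original, lost, rate, state."""
        return pd.DataFrame({
            "bin": np.arange(self.lost_per_bin.size),
            "original": self.original_per_bin,
            "lost": self.lost_per_bin,
            "rate": loss_rate_series(self),
            "state": np.where(self.mask, "bad", "good"),
        })


@dataclass
class GEParams:
    """Gilbert-Elliott channel parameters (per-bin transition probabilities).

    ``p_gb`` = P(Good -> Bad), ``q_bg`` = P(Bad -> Good); the stationary
    loss probability is ``p_gb / (p_gb + q_bg)`` (equivalently
    ``1 - q/(p+q)``).  ``loss_fraction_in_bad`` is the fraction of a Bad
    bin's spikes dropped (1.0 = whole row zeroed, the default severity).
    """

    p_gb: float
    q_bg: float
    loss_fraction_in_bad: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_gb", "q_bg", "loss_fraction_in_bad"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")

    @property
    def stationary_loss(self) -> float:
        s = self.p_gb + self.q_bg
        return self.p_gb / s if s > 0 else 0.0


@dataclass
class CongestionParams:
    """Bandwidth cap: at most ``bandwidth_Z`` packets transmitted per bin."""

    bandwidth_Z: int

    def __post_init__(self) -> None:
        if self.bandwidth_Z < 0 or int(self.bandwidth_Z) != self.bandwidth_Z:
            raise ValueError("bandwidth_Z must be a non-negative integer")
        self.bandwidth_Z = int(self.bandwidth_Z)


@dataclass
class DistributedParams:
    """Nominal rate for the distributed (single/full) loss models.

    ``mode`` selects how the single-loss event budget L is set and drawn:
    ``"paper_literal"`` uses L = round(p * N * C) with uniform draws over
    positive entries; ``"spike_fraction"`` uses L = round(p * total spikes)
    with count-weighted (spike-uniform) draws, making the achieved spike
    loss exactly p.
    """

    rate_p: float
    mode: str = "paper_literal"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate_p <= 1.0:
            raise ValueError(f"rate_p={self.rate_p} must lie in [0, 1]")
        if self.mode not in ("paper_literal", "spike_fraction"):
            raise ValueError("mode must be 'paper_literal' or 'spike_fraction'")


def _report(A: CountMatrix, out: np.ndarray, mask: np.ndarray,
            name: str, params: dict[str, Any]) -> LossReport:
    orig = A.counts.sum(axis=1)
    lost = orig - out.sum(axis=1)
    return LossReport(lost_per_bin=lost, original_per_bin=orig, mask=mask,
                      model_name=name, params=params)


def congestion_loss(A: CountMatrix, ev: SpikeEvents,
                    cp: CongestionParams) -> tuple[CountMatrix, LossReport]:
    """Drop every spike past the first ``Z`` (in arrival order) of each bin.

    ``ev`` supplies the within-bin arrival times; it must bin back to ``A``
    exactly.  Ties in arrival time are broken by ascending unit index.
    After corruption each row sums to ``min(X_i, Z)``.
    """
    Z = cp.bandwidth_Z
    times, owners = ev.flatten()
    bins = np.floor((times - A.t0) / A.bin_width_s).astype(int)
    if (np.any(bins < 0) or np.any(bins >= A.n_bins)
            or ev.n_units != A.n_units):
        raise ValueError("spike events do not match the count matrix span")
    check = np.zeros_like(A.counts)
    np.add.at(check, (bins, owners), 1)
    if not np.array_equal(check, A.counts):
        raise ValueError("spike events are inconsistent with the count matrix")

    order = np.lexsort((owners, times, bins))  # bin-major, then time, then unit
    b_sorted = bins[order]
    # arrival rank of each spike within its bin
    first = np.r_[True, b_sorted[1:] != b_sorted[:-1]]
    seg_start = np.maximum.accumulate(np.where(first, np.arange(b_sorted.size), 0))
    rank = np.arange(b_sorted.size) - seg_start
    keep = rank < Z
    out = np.zeros_like(A.counts)
    np.add.at(out, (b_sorted[keep], owners[order][keep]), 1)
    mask = np.zeros(A.n_bins, dtype=bool)
    corrupted = CountMatrix(out, A.bin_width_s, A.t0)
    return corrupted, _report(A, out, mask, "congestion", {"bandwidth_Z": Z})


def full_loss(A: CountMatrix,
              dp: DistributedParams) -> tuple[CountMatrix, LossReport]:
    """Zero ``L = round(p*N)`` uniformly chosen distinct rows (whole bins)."""
    rng = np.random.default_rng(dp.seed)
    L = _round_half_away(dp.rate_p * A.n_bins)
    rows = rng.choice(A.n_bins, size=L, replace=False)
    out = A.counts.copy()
    out[rows] = 0
    mask = np.zeros(A.n_bins, dtype=bool)
    mask[rows] = True
    corrupted = CountMatrix(out, A.bin_width_s, A.t0)
    return corrupted, _report(A, out, mask, "full",
                              {"rate_p": dp.rate_p, "L": L})


def single_loss(A: CountMatrix,
                dp: DistributedParams) -> tuple[CountMatrix, LossReport]:
    """Remove ``L`` individual spikes, one random positive entry at a time.

    In ``paper_literal`` mode ``L = round(p * N * C)`` and each decrement
    hits a uniformly random currently-positive entry; in
    ``spike_fraction`` mode ``L = round(p * total)`` and spikes are removed
    uniformly over the spike population (count-weighted entries).

    Raises
    ------
    ValueError
        If L exceeds the spikes available.
    """
    rng = np.random.default_rng(dp.seed)
    total = A.total_spikes
    if dp.mode == "paper_literal":
        L = _round_half_away(dp.rate_p * A.n_bins * A.n_units)
    else:
        L = _round_half_away(dp.rate_p * total)
    if L > total:
        raise ValueError(
            f"cannot remove L={L} spikes: only {total} present "
            f"(shortfall {L - total})")
    out = A.counts.copy()
    if dp.mode == "spike_fraction":
        removed = rng.multivariate_hypergeometric(out.ravel(), L)
        out = (out.ravel() - removed).reshape(out.shape)
    else:
        flat = out.ravel()
        positive = np.flatnonzero(flat).tolist()  # swap-remove keeps O(1) steps
        for _ in range(L):
            i = int(rng.integers(len(positive)))
            p = positive[i]
            flat[p] -= 1
            if flat[p] == 0:
                positive[i] = positive[-1]
                positive.pop()
        out = flat.reshape(out.shape)
    mask = np.zeros(A.n_bins, dtype=bool)
    corrupted = CountMatrix(out, A.bin_width_s, A.t0)
    return corrupted, _report(A, out, mask, "single",
                              {"rate_p": dp.rate_p, "mode": dp.mode, "L": L})


def burst_loss(A: CountMatrix, ge: GEParams) -> tuple[CountMatrix, LossReport]:
    """Gilbert-Elliott burst corruption over the bin sequence.

    The chain starts in the Good state.  Each Bad bin loses
    ``loss_fraction_in_bad`` of its spikes (the whole row at the default
    severity 1.0; fractions < 1 remove a spike-uniform subset of
    ``round(f * X_i)`` spikes).  The mask marks Bad bins.
    """
    rng = np.random.default_rng(ge.seed)
    N = A.n_bins
    u = rng.random(N)
    bad = np.zeros(N, dtype=bool)
    state = False  # bin 0 carries the initial Good state
    for i in range(1, N):
        state = (u[i] < ge.p_gb) if not state else (u[i] >= ge.q_bg)
        bad[i] = state
    out = A.counts.copy()
    if ge.loss_fraction_in_bad >= 1.0:
        out[bad] = 0
    else:
        for i in np.flatnonzero(bad):
            row = out[i]
            k = _round_half_away(ge.loss_fraction_in_bad * row.sum())
            if k > 0:
                out[i] = row - rng.multivariate_hypergeometric(row, k)
    corrupted = CountMatrix(out, A.bin_width_s, A.t0)
    return corrupted, _report(A, out, bad, "burst", {
        "p_gb": ge.p_gb, "q_bg": ge.q_bg,
        "loss_fraction_in_bad": ge.loss_fraction_in_bad})


def ge_params_from(p_loss: float, mean_burst_len: float,
                   loss_fraction_in_bad: float = 1.0,
                   seed: int | None = None) -> GEParams:
    """Solve the Gilbert-Elliott transition probabilities for a target
    stationary loss rate and mean burst length.

    With stationary loss ``p/(p+q)`` and mean Bad-dwell ``1/q``:
    ``q_bg = 1/mean_burst_len`` and ``p_gb = p_loss*q_bg/(1-p_loss)``.
    The round trip ``p_gb/(p_gb+q_bg) == p_loss`` holds to machine
    precision.
    """
    if not 0.0 < p_loss < 1.0:
        raise ValueError("p_loss must lie strictly in (0, 1)")
    if mean_burst_len < 1.0:
        raise ValueError("mean_burst_len must be >= 1")
    q = 1.0 / mean_burst_len
    p = p_loss * q / (1.0 - p_loss)
    if p > 1.0:
        raise ValueError(
            f"p_loss={p_loss} with mean_burst_len={mean_burst_len} requires "
            f"p_gb={p:.3g} > 1; increase mean_burst_len")
    return GEParams(p_gb=p, q_bg=q, loss_fraction_in_bad=loss_fraction_in_bad,
                    seed=seed)


def _congestion_rate(row_sums: np.ndarray, Z: int) -> float:
    total = row_sums.sum()
    return float(np.maximum(row_sums - Z, 0).sum() / total) if total else 0.0


def calibrate_bandwidth(A: CountMatrix, target_rate: float) -> CongestionParams:
    """Find the integer bandwidth Z whose congestion loss rate is closest to
    ``target_rate``.

    The achieved rate ``sum(max(X_i - Z, 0)) / sum(X_i)`` is non-increasing
    in Z, so a bisection over ``[0, max X_i]`` locates the crossing; the
    better of the two straddling integers is returned.
    """
    if not 0.0 <= target_rate < 1.0:
        raise ValueError("target_rate must lie in [0, 1)")
    X = A.counts.sum(axis=1)
    if X.sum() == 0:
        raise ValueError("cannot calibrate on an empty matrix")
    lo, hi = 0, int(X.max())  # rate(lo)=1 >= target > possibly rate(hi)=0
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _congestion_rate(X, mid) > target_rate:
            lo = mid
        else:
            hi = mid
    Z = min((lo, hi), key=lambda z: abs(_congestion_rate(X, z) - target_rate))
    if target_rate == 0.0:
        Z = int(X.max())
    return CongestionParams(bandwidth_Z=Z)


def loss_rate_series(report: LossReport) -> np.ndarray:
    """Per-bin loss rate ``lost_i / original_i`` (0 where the bin was empty)."""
    orig = report.original_per_bin
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(orig > 0, report.lost_per_bin / np.maximum(orig, 1), 0.0)
    return r.astype(float)
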