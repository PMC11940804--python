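"""Synthetic reach kinematics and linearly tuned Poisson spike counts.

Emulates a self-paced centre-out-style session: a sequence of
point-to-point reaches between targets on a square grid (8 x 8 by
default), with minimum-jerk trajectories and brief holds at each target.
Spike counts per bin are Poisson with a rectified linear dependence on
the 6-D kinematic state (position, velocity, acceleration in x and y),
the tuning structure the downstream decoder assumes.

The bin width defaults to 128 ms, the binning used throughout the
analysis, and the unit count defaults to 576 (192 channels x 3 sorted
spike types in the emulated recordings); both are configurable, and
tests run far smaller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ingest import CountMatrix, SpikeEvents

__all__ = [
    "ReachConfig",
    "TuningModel",
    "Kinematics",
    "minimum_jerk",
    "generate_kinematics",
    "generate_spikes",
]

#: canonical ordering of the kinematic state vector
STATE_LABELS = ("pos_x", "pos_y", "vel_x", "vel_y", "acc_x", "acc_y")


@dataclass
class ReachConfig:
    """Parameters of the simulated reaching session.

    grid_size
        Targets per side of the square grid (>= 2).
    grid_spacing_m
        Distance between adjacent targets, metres.
    reach_duration_s
        Movement time of one point-to-point reach.
    hold_s
        Stationary hold at each target between reaches.
    session_length_s
        Total session duration.
    bin_width_s
        Width of the counting/sampling bin (seconds).
    """

    grid_size: int = 8
    grid_spacing_m: float = 0.05
    reach_duration_s: float = 0.8
    hold_s: float = 0.2
    session_length_s: float = 640.0
    bin_width_s: float = 0.128
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.bin_width_s <= 0:
            raise ValueError("bin_width_s must be positive")
        if self.session_length_s < self.bin_width_s:
            raise ValueError("session_length_s must cover at least one bin")
        if self.reach_duration_s <= 0 or self.hold_s < 0:
            raise ValueError("reach_duration_s must be > 0 and hold_s >= 0")

    @property
    def n_bins(self) -> int:
        return int(np.floor(self.session_length_s / self.bin_width_s))


@dataclass
class Kinematics:
    """Binned 6-D kinematic state.

    ``times`` are bin-start timestamps (s); ``states`` is N x 6 ordered
    (pos_x, pos_y, vel_x, vel_y, acc_x, acc_y) in m, m/s, m/s^2, sampled
    at bin centres.  Velocity and acceleration are the discrete
    (central-difference) derivatives of the sampled position.
    """

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape[1] != 6:
            raise ValueError("states must be N x 6")
        if self.states.shape[0] != self.times.size:
            raise ValueError("times and states must have equal length")

    @property
    def n_bins(self) -> int:
        return self.states.shape[0]

    @property
    def position(self) -> np.ndarray:
        return self.states[:, 0:2]

    @property
    def velocity(self) -> np.ndarray:
        return self.states[:, 2:4]

    @property
    def acceleration(self) -> np.ndarray:
        return self.states[:, 4:6]


@dataclass
class TuningModel:
    """Rectified-linear Poisson tuning: count_ij ~ Poisson(max(0, b_j + H_j . x_i)).

    ``baseline`` is the per-unit baseline rate in spikes per bin; ``gains``
    is the C x 6 coefficient matrix H mapping the kinematic state to the
    expected count.  Only Poisson count noise is supported.
    """

    n_units: int = 576
    baseline: np.ndarray = field(default=None)  # type: ignore[assignment]
    gains: np.ndarray = field(default=None)  # type: ignore[assignment]
    noise: str = "poisson"

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.noise != "poisson":
            raise ValueError("only 'poisson' noise is supported")
        if self.baseline is None:
            self.baseline = np.ones(self.n_units)
        self.baseline = np.broadcast_to(
            np.asarray(self.baseline, dtype=float), (self.n_units,)).copy()
        if np.any(self.baseline < 0):
            raise ValueError("baseline must be non-negative")
        if self.gains is None:
            self.gains = np.zeros((self.n_units, 6))
        self.gains = np.asarray(self.gains, dtype=float)
        if self.gains.shape != (self.n_units, 6):
            raise ValueError("gains must be n_units x 6")
        if not np.all(np.isfinite(self.gains)):
            raise ValueError("gains must be finite")

    @classmethod
    def random(cls, n_units: int, cfg: ReachConfig, seed: int | None = None,
               baseline: float = 1.0, modulation: float = 0.3) -> "TuningModel":
        """Draw a random tuning model scaled to the session's kinematics.

        Each unit gets independent Gaussian gains, normalised per kinematic
        dimension so one standard deviation of that dimension modulates the
        expected count by ``modulation * baseline`` spikes/bin.  With the
        defaults the mean count is ~1 spike/bin/unit and the population is
        informative about all six dimensions.
        """
        rng = np.random.default_rng(seed)
        # per-dimension scale from a short reference session with the same
        # reach geometry (kinematic magnitudes, not the realised targets)
        ref_cfg = ReachConfig(
            grid_size=cfg.grid_size, grid_spacing_m=cfg.grid_spacing_m,
            reach_duration_s=cfg.reach_duration_s, hold_s=cfg.hold_s,
            session_length_s=max(100.0, 10 * (cfg.reach_duration_s + cfg.hold_s)),
            bin_width_s=cfg.bin_width_s, seed=12345)
        ref = generate_kinematics(ref_cfg)
        scale = ref.states.std(axis=0)
        scale[scale == 0] = 1.0
        gains = modulation * baseline * rng.standard_normal((n_units, 6)) / scale
        return cls(n_units=n_units, baseline=np.full(n_units, float(baseline)),
                   gains=gains)


def minimum_jerk(x0: np.ndarray, x1: np.ndarray, T: float, t: np.ndarray):
    """Minimum-jerk point-to-point trajectory and its analytic derivatives.

    Position follows the quintic ``x0 + (x1-x0)(10 s^3 - 15 s^4 + 6 s^5)``
    with ``s = t/T``, giving zero velocity and acceleration at both
    endpoints.  ``t`` outside ``[0, T]`` is clamped to the endpoints.

    Returns ``(pos, vel, acc)`` with shapes ``t.shape + x0.shape``.
    """
    if T <= 0:
        raise ValueError("reach duration T must be positive")
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    s = np.clip(np.asarray(t, dtype=float) / T, 0.0, 1.0)
    s = s[..., np.newaxis] if x0.ndim else s
    d = x1 - x0
    pos = x0 + d * (10 * s**3 - 15 * s**4 + 6 * s**5)
    vel = d * (30 * s**2 - 60 * s**3 + 30 * s**4) / T
    acc = d * (60 * s - 180 * s**2 + 120 * s**3) / T**2
    return pos, vel, acc


def _target_sequence(cfg: ReachConfig, rng: np.random.Generator,
                     n_reaches: int) -> np.ndarray:
    """Uniformly drawn grid targets, resampling immediate repeats."""
    g = cfg.grid_size
    idx = np.empty(n_reaches + 1, dtype=int)
    idx[0] = rng.integers(g * g)
    for k in range(1, n_reaches + 1):
        nxt = rng.integers(g * g)
        while nxt == idx[k - 1]:
            nxt = rng.integers(g * g)
        idx[k] = nxt
    xy = np.column_stack([idx % g, idx // g]) * cfg.grid_spacing_m
    return xy - xy.mean(axis=0).round(6)  # roughly centre the workspace


def generate_kinematics(cfg: ReachConfig,
                        targets: Sequence[Sequence[float]] | None = None) -> Kinematics:
    """Simulate a session of minimum-jerk grid reaches and sample it in bins.

    Each cycle is a hold of ``cfg.hold_s`` at the current target followed by
    a minimum-jerk reach of ``cfg.reach_duration_s`` to the next uniformly
    drawn target (immediate repeats resampled).  Position is evaluated at
    bin centres; velocity and acceleration are central finite differences
    of the sampled position, so the three blocks are discretely consistent.

    Parameters
    ----------
    targets : optional (n_reaches+1) x 2 array
        Explicit waypoint override (e.g. a degenerate stationary session);
        bypasses random target draws.
    """
    rng = np.random.default_rng(cfg.seed)
    cycle = cfg.reach_duration_s + cfg.hold_s
    n_reaches = int(np.ceil(cfg.session_length_s / cycle))
    if n_reaches < 1 or cfg.session_length_s < cycle:
        raise ValueError(
            f"session_length_s={cfg.session_length_s} shorter than one "
            f"reach cycle ({cycle} s)")
    if targets is None:
        waypoints = _target_sequence(cfg, rng, n_reaches)
    else:
        waypoints = np.asarray(targets, dtype=float)
        if waypoints.ndim != 2 or waypoints.shape[1] != 2 or len(waypoints) < n_reaches + 1:
            raise ValueError(
                f"targets must be at least {n_reaches + 1} x 2 waypoints")

    N = cfg.n_bins
    t_centre = (np.arange(N) + 0.5) * cfg.bin_width_s
    pos = np.empty((N, 2))
    # piecewise schedule: [hold at waypoint k][reach k -> k+1], repeated
    seg = np.floor(t_centre / cycle).astype(int)
    seg = np.minimum(seg, n_reaches - 1)
    t_in = t_centre - seg * cycle
    for k in range(n_reaches):
        m = seg == k
        if not m.any():
            continue
        tk = t_in[m] - cfg.hold_s  # negative during hold -> clamped to start
        pos[m] = minimum_jerk(waypoints[k], waypoints[k + 1],
                              cfg.reach_duration_s, tk)[0]
    dt = cfg.bin_width_s
    vel = np.gradient(pos, dt, axis=0)
    acc = np.gradient(vel, dt, axis=0)
    states = np.hstack([pos, vel, acc])
    times = np.arange(N) * cfg.bin_width_s
    return Kinematics(times=times, states=states)


def generate_spikes(kin: Kinematics, tuning: TuningModel,
                    seed: int | None = None) -> tuple[SpikeEvents, CountMatrix]:
    """Draw Poisson spike counts from the rectified-linear tuning model.

    Per bin ``i`` and unit ``j`` the count is
    ``Poisson(max(0, baseline_j + gains_j . state_i))``; each counted
    spike is then placed at an i.i.d. uniform time inside its bin so the
    congestion loss model has a within-bin arrival order.  Re-binning the
    emitted events reproduces the emitted count matrix exactly.
    """
    if tuning.gains.shape[0] != tuning.n_units:
        raise ValueError("tuning gains inconsistent with n_units")
    rng = np.random.default_rng(seed)
    rates = np.maximum(0.0, tuning.baseline[np.newaxis, :]
                       + kin.states @ tuning.gains.T)
    counts = rng.poisson(rates)
    if kin.times.size > 1:
        dt = float(kin.times[1] - kin.times[0])
    else:
        dt = 1.0
    A = CountMatrix(counts, bin_width_s=dt, t0=float(kin.times[0]))
    units = []
    starts = A.bin_starts()
    for j in range(A.n_units):
        c = counts[:, j]
        t = np.repeat(starts, c) + dt * rng.random(int(c.sum()))
        units.append(np.sort(t))
    S = 3 if tuning.n_units % 3 == 0 else 1
    ev = SpikeEvents(units,
                     channel=np.arange(tuning.n_units) // S,
                     spike_type=np.arange(tuning.n_units) % S)
    return ev, A
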