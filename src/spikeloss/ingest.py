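"""Spike-event containers and binning into the N x C count matrix.

Raw multielectrode recordings arrive as spike timestamps organised by
physical channel and sorted spike type (unit).  Decoding operates on a
matrix ``A`` of shape ``N x C`` whose entry ``A[i, j]`` counts the spikes
of unit ``j`` inside time bin ``i``.  This module reshapes channel x type
event tables into flat per-unit streams and bins them.

Bins are half-open, 0-based: bin ``i`` covers ``[t0 + i*dt, t0 + (i+1)*dt)``.
Units are ordered channel-major over spike types: ``u = channel * S + type``
where ``S`` is the number of spike types per channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeEvents",
    "CountMatrix",
    "reshape_units",
    "bin_spikes",
    "events_from_counts",
    "read_session",
]


@dataclass
class SpikeEvents:
    """Per-unit spike timestamp streams (the packetised raw signal).

    Parameters
    ----------
    units : list of 1-D float arrays
        Ascending spike times in seconds, one array per unit.
    channel, spike_type : int arrays, optional
        Source physical channel and sorted-unit index of each stream.
    """

    units: list[np.ndarray]
    channel: np.ndarray = field(default=None)  # type: ignore[assignment]
    spike_type: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.units = [np.asarray(u, dtype=float).ravel() for u in self.units]
        for j, u in enumerate(self.units):
            if u.size > 1 and np.any(np.diff(u) < 0):
                raise ValueError(f"unit {j}: spike times must be ascending")
        if self.channel is None:
            self.channel = np.arange(len(self.units), dtype=int)
        if self.spike_type is None:
            self.spike_type = np.zeros(len(self.units), dtype=int)
        self.channel = np.asarray(self.channel, dtype=int)
        self.spike_type = np.asarray(self.spike_type, dtype=int)
        if len(self.channel) != len(self.units) or len(self.spike_type) != len(self.units):
            raise ValueError("channel/spike_type metadata length must match unit count")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_spikes(self) -> int:
        return int(sum(u.size for u in self.units))

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        """All spikes as parallel (times, unit_index) arrays, unit-major order."""
        if self.n_units == 0:
            return np.empty(0), np.empty(0, dtype=int)
        times = np.concatenate(self.units) if self.n_spikes else np.empty(0)
        owners = np.repeat(np.arange(self.n_units), [u.size for u in self.units])
        return times, owners


@dataclass
class CountMatrix:
    """Binned spike counts: ``counts[i, j]`` = spikes of unit j in bin i.

    ``bin_width_s`` is the bin width (128 ms by default throughout the
    package) and ``t0`` the time origin of bin 0.
    """

    counts: np.ndarray
    bin_width_s: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D (bins x units) array")
        if self.bin_width_s <= 0:
            raise ValueError("bin_width_s must be positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    @property
    def total_spikes(self) -> int:
        return int(self.counts.sum())

    def bin_starts(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_bins) * self.bin_width_s

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.bin_width_s, self.t0)


def reshape_units(raw: Sequence[Sequence[np.ndarray]]) -> SpikeEvents:
    """Flatten a rectangular channel x spike-type event table into per-unit streams.

    The flat unit index is ``u = channel * S + type`` with ``S`` the number
    of spike types, so e.g. 192 channels x 3 types yield 576 units and
    unit 4 is (channel 1, type 1).  Empty event lists are preserved.

    Raises
    ------
    ValueError
        If the table is ragged (rows with differing numbers of types).
    """
    if len(raw) == 0:
        raise ValueError("empty channel table")
    n_types = len(raw[0])
    if any(len(row) != n_types for row in raw):
        raise ValueError("ragged channel x type structure: all channels must have "
                         "the same number of spike types")
    units, channel, spike_type = [], [], []
    for c, row in enumerate(raw):
        for s, ev in enumerate(row):
            units.append(np.sort(np.asarray(ev, dtype=float).ravel()))
            channel.append(c)
            spike_type.append(s)
    return SpikeEvents(units, np.array(channel), np.array(spike_type))


def bin_spikes(ev: SpikeEvents, bin_width_s: float, t0: float = 0.0,
               n_bins: int | None = None) -> CountMatrix:
    """Count spikes of each unit in half-open bins ``[t0+i*dt, t0+(i+1)*dt)``.

    Spikes before ``t0`` or at/after the last bin edge are dropped; the
    number dropped is logged.  If ``n_bins`` is omitted it is chosen to
    cover every event.
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    if n_bins is None:
        tmax = max((u[-1] for u in ev.units if u.size), default=t0)
        n_bins = max(int(np.floor((tmax - t0) / bin_width_s)) + 1, 1)
    counts = np.zeros((n_bins, ev.n_units), dtype=np.int64)
    dropped = 0
    for j, u in enumerate(ev.units):
        idx = np.floor((u - t0) / bin_width_s).astype(int)
        ok = (idx >= 0) & (idx < n_bins)
        dropped += int((~ok).sum())
        counts[:, j] = np.bincount(idx[ok], minlength=n_bins)
    if dropped:
        logger.info("bin_spikes: dropped %d out-of-range spikes", dropped)
    return CountMatrix(counts, bin_width_s, t0)


def events_from_counts(A: CountMatrix, rng: np.random.Generator | int | None = None) -> SpikeEvents:
    """Place each counted spike at an i.i.d. uniform time inside its bin.

    Inverse of :func:`bin_spikes` up to within-bin timing: re-binning the
    result at ``A.bin_width_s`` reproduces ``A`` exactly.
    """
    rng = np.random.default_rng(rng)
    starts = A.bin_starts()
    units = []
    for j in range(A.n_units):
        c = A.counts[:, j]
        t = np.repeat(starts, c) + A.bin_width_s * rng.random(int(c.sum()))
        units.append(np.sort(t))
    return SpikeEvents(units)


def read_session(path: str) -> tuple[list[list[np.ndarray]], np.ndarray, np.ndarray]:
    """Read a recorded-session HDF5 container (channel x type spike-time cells
    plus cursor kinematics).

    Expects datasets ``spikes`` (2-D array of object references to per-unit
    time vectors, channels x types or its transpose), ``cursor_pos``
    (2 x T or T x 2 positions) and ``t`` (T sample times).  Returns the raw
    channel x type event table (feed to :func:`reshape_units`), cursor
    positions as T x 2, and the T sample times.
    """
    with h5py.File(path, "r") as f:
        spikes = f["spikes"]
        refs = np.asarray(spikes)
        if refs.ndim != 2:
            raise ValueError("spikes dataset must be 2-D (channels x types)")
        # MATLAB v7.3 stores cell arrays transposed; orient channels-major
        # (more channels than spike types in any real array).
        if refs.shape[0] < refs.shape[1]:
            refs = refs.T
        raw: list[list[np.ndarray]] = []
        for c in range(refs.shape[0]):
            row = []
            for s in range(refs.shape[1]):
                node = f[refs[c, s]] if isinstance(refs[c, s], h5py.Reference) else refs[c, s]
                row.append(np.asarray(node, dtype=float).ravel())
            raw.append(row)
        cursor = np.asarray(f["cursor_pos"], dtype=float)
        if cursor.shape[0] == 2 and cursor.shape[-1] != 2:
            cursor = cursor.T
        t = np.asarray(f["t"], dtype=float).ravel()
    return raw, cursor, t
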