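"""HDF5/CSV persistence for the core containers and YAML/JSON configs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .ingest import CountMatrix, SpikeEvents
from .kalman import DecoderSpec
from .synthetic import Kinematics, ReachConfig, STATE_LABELS

__all__ = [
    "save_counts", "load_counts", "save_kinematics", "load_kinematics",
    "save_events", "load_events", "counts_to_csv", "kinematics_to_csv",
    "load_experiment_config",
]


def save_counts(A: CountMatrix, path: str) -> None:
    with h5py.File(path, "a") as f:
        if "counts" in f:
            del f["counts"]
        g = f.create_group("counts")
        g.create_dataset("A", data=A.counts, compression="gzip")
        g.attrs["bin_width_s"] = A.bin_width_s
        g.attrs["t0"] = A.t0


def load_counts(path: str) -> CountMatrix:
    with h5py.File(path, "r") as f:
        g = f["counts"]
        return CountMatrix(np.asarray(g["A"]), float(g.attrs["bin_width_s"]),
                           float(g.attrs["t0"]))


def save_kinematics(kin: Kinematics, path: str) -> None:
    with h5py.File(path, "a") as f:
        if "kinematics" in f:
            del f["kinematics"]
        g = f.create_group("kinematics")
        g.create_dataset("times", data=kin.times)
        g.create_dataset("states", data=kin.states)


def load_kinematics(path: str) -> Kinematics:
    with h5py.File(path, "r") as f:
        g = f["kinematics"]
        return Kinematics(np.asarray(g["times"]), np.asarray(g["states"]))


def save_events(ev: SpikeEvents, path: str) -> None:
    """Ragged per-unit spike-time arrays under ``events/unit_<j>``."""
    with h5py.File(path, "a") as f:
        if "events" in f:
            del f["events"]
        g = f.create_group("events")
        g.attrs["n_units"] = ev.n_units
        g.create_dataset("channel", data=ev.channel)
        g.create_dataset("spike_type", data=ev.spike_type)
        for j, u in enumerate(ev.units):
            g.create_dataset(f"unit_{j}", data=u)


def load_events(path: str) -> SpikeEvents:
    with h5py.File(path, "r") as f:
        g = f["events"]
        n = int(g.attrs["n_units"])
        units = [np.asarray(g[f"unit_{j}"]) for j in range(n)]
        return SpikeEvents(units, channel=np.asarray(g["channel"]),
                           spike_type=np.asarray(g["spike_type"]))


def counts_to_csv(A: CountMatrix, path: str) -> None:
    df = pd.DataFrame(A.counts, columns=[f"u{j}" for j in range(A.n_units)])
    df.insert(0, "t", A.bin_starts())
    df.to_csv(path, index=False)


def kinematics_to_csv(kin: Kinematics, path: str) -> None:
    df = pd.DataFrame(kin.states, columns=list(STATE_LABELS))
    df.insert(0, "t", kin.times)
    df.to_csv(path, index=False)


def load_experiment_config(path: str):
    """Hydrate an :class:`~spikeloss.experiment.ExperimentConfig` from YAML/JSON."""
    from .experiment import ExperimentConfig

    text = Path(path).read_text()
    raw = json.loads(text) if path.endswith(".json") else yaml.safe_load(text)
    raw = dict(raw or {})
    if "reach" in raw:
        raw["reach"] = ReachConfig(**raw["reach"])
    if "decoder" in raw:
        raw["decoder"] = DecoderSpec(**raw["decoder"])
    for key in ("models", "rates"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ExperimentConfig(**raw)


def dump_experiment_config(cfg, path: str) -> None:
    d = asdict(cfg)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
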