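"""Full-analysis orchestration: sweep loss model x rate x replicate and score.

A run generates (or accepts) a synthetic session, splits it into a clean
training segment and a test segment, fits the decoder on the clean
training data, then for every (loss model, nominal rate, replicate)
corrupts *only the test-segment transmission*, decodes and scores it.
Training data are never corrupted: the sweep isolates what transmission
loss does to a decoder that was calibrated under good conditions, the
deployed-interface scenario.

Every run's seed and achieved loss rate are logged in the output tables,
and the whole sweep is byte-reproducible from (config, base seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, loss
from .ingest import CountMatrix, SpikeEvents
from .kalman import DecoderSpec, DecodeResult, get_decoder_factory
from .synthetic import (Kinematics, ReachConfig, TuningModel,
                        generate_kinematics, generate_spikes, STATE_LABELS)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "reconstruct_trace", "DEFAULT_RATES", "DEFAULT_MODELS"]

#: nominal loss-rate grid spanning the 0-10% range studied
DEFAULT_RATES = (0.0, 0.005, 0.01, 0.02, 0.03, 0.05, 0.07, 0.10)
DEFAULT_MODELS = ("congestion", "single", "full", "burst")


@dataclass
class ExperimentConfig:
    """Declarative description of one degradation sweep."""

    reach: ReachConfig = field(default_factory=ReachConfig)
    n_units: int = 576
    baseline_rate: float = 1.0
    modulation: float = 0.3
    models: tuple[str, ...] = DEFAULT_MODELS
    rates: tuple[float, ...] = DEFAULT_RATES
    replicates: int = 5
    base_seed: int = 0
    decoder: DecoderSpec = field(default_factory=DecoderSpec)
    mean_burst_len: float = 2.0
    single_mode: str = "paper_literal"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if any(not 0.0 <= r <= 0.5 for r in self.rates):
            raise ValueError("loss rates must lie within [0, 0.5]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = set(self.models) - set(DEFAULT_MODELS)
        if unknown:
            raise ValueError(f"unknown loss models: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        d["rates"] = list(self.rates)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    """Everything a sweep produces, in memory."""

    r2_table: pd.DataFrame
    loss_table: pd.DataFrame
    baseline: DecodeResult
    traces: dict[tuple[str, float], DecodeResult]
    curves: pd.DataFrame
    config_hash: str

    def write(self, out_dir: str) -> None:
        """Write tidy CSV outputs (deterministic bytes for a fixed config)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.r2_table.to_csv(out / "r2_table.csv", index=False, float_format="%.10g")
        self.loss_table.to_csv(out / "loss_table.csv", index=False, float_format="%.10g")
        self.curves.to_csv(out / "curves.csv", index=False, float_format="%.10g")


def _run_seed(base: int, model: str, rate_idx: int, rep: int) -> int:
    """Stable per-run seed < 2^31, independent of sweep iteration order."""
    ss = np.random.SeedSequence(
        [base, DEFAULT_MODELS.index(model), rate_idx, rep])
    return int(ss.generate_state(1)[0] % (2**31))


def apply_loss(model: str, A: CountMatrix, ev: SpikeEvents | None,
               rate: float, seed: int | None, *, mean_burst_len: float = 2.0,
               single_mode: str = "paper_literal",
               congestion_Z: int | None = None):
    """Dispatch one loss model at a nominal rate; returns (corrupted, report).

    For the congestion model a pre-calibrated bandwidth ``congestion_Z``
    may be supplied (the sweep calibrates once per rate on the clean test
    matrix); otherwise it is calibrated here.
    """
    if model == "full":
        return loss.full_loss(A, loss.DistributedParams(rate, seed=seed))
    if model == "single":
        return loss.single_loss(
            A, loss.DistributedParams(rate, mode=single_mode, seed=seed))
    if model == "burst":
        if rate == 0:
            ge = loss.GEParams(p_gb=0.0, q_bg=1.0, seed=seed)
        else:
            ge = loss.ge_params_from(rate, mean_burst_len, seed=seed)
        return loss.burst_loss(A, ge)
    if model == "congestion":
        if ev is None:
            raise ValueError("congestion loss needs spike events")
        cp = (loss.CongestionParams(congestion_Z) if congestion_Z is not None
              else loss.calibrate_bandwidth(A, rate))
        return loss.congestion_loss(A, ev, cp)
    raise ValueError(f"unknown loss model '{model}'")


def _slice_events(ev: SpikeEvents, t_lo: float, t_hi: float) -> SpikeEvents:
    units = [u[(u >= t_lo) & (u < t_hi)] for u in ev.units]
    return SpikeEvents(units, channel=ev.channel, spike_type=ev.spike_type)


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Execute the sweep described by ``cfg``.

    Returns the tidy per-replicate R^2 table (a clean no-loss baseline row
    first, then one row per model x nonzero rate x replicate), a per-run
    loss-accounting table, the baseline decode, one stored reconstruction
    trace per (model, rate) for plotting, and the aggregated degradation
    curves.
    """
    ss = np.random.SeedSequence([cfg.base_seed, 0xDA7A])
    kin_seed, tune_seed, spike_seed = (int(s) % (2**31)
                                       for s in ss.generate_state(3))
    reach = ReachConfig(**{**asdict(cfg.reach), "seed": kin_seed})
    kin = generate_kinematics(reach)
    tuning = TuningModel.random(cfg.n_units, reach, seed=tune_seed,
                                baseline=cfg.baseline_rate,
                                modulation=cfg.modulation)
    ev, counts = generate_spikes(kin, tuning, seed=spike_seed)

    n_train = int(round(cfg.decoder.train_seconds / reach.bin_width_s))
    if not 2 <= n_train <= counts.n_bins - 2:
        raise ValueError(
            f"train split of {n_train} bins leaves no usable test segment "
            f"(session has {counts.n_bins} bins)")
    split_t = counts.t0 + n_train * counts.bin_width_s
    train_counts = CountMatrix(counts.counts[:n_train], counts.bin_width_s, counts.t0)
    test_counts = CountMatrix(counts.counts[n_train:], counts.bin_width_s, split_t)
    train_kin = Kinematics(kin.times[:n_train], kin.states[:n_train])
    test_kin = Kinematics(kin.times[n_train:], kin.states[n_train:])
    test_ev = _slice_events(ev, split_t, split_t + test_counts.n_bins * counts.bin_width_s)

    factory = get_decoder_factory(cfg.decoder.name)
    fitted = factory(cfg.decoder, train_counts, train_kin).fit()

    baseline = fitted.score(test_counts, test_kin)
    rows: list[dict] = []
    loss_rows: list[dict] = []
    traces: dict[tuple[str, float], DecodeResult] = {}

    def r2_row(model: str, rate: float, rep: int, seed: int,
               achieved: float, res: DecodeResult) -> dict:
        row = {"model": model, "loss_rate": rate, "replicate": rep,
               "seed": seed, "achieved_rate": achieved}
        row.update({f"r2_{d}": res.r2[i] for i, d in enumerate(STATE_LABELS)})
        return row

    rows.append(r2_row("none", 0.0, 0, cfg.base_seed, 0.0, baseline))
    traces[("none", 0.0)] = baseline

    # calibrate congestion bandwidth once per nominal rate on the clean test data
    z_for_rate = {}
    if "congestion" in cfg.models:
        for rate in cfg.rates:
            if rate > 0:
                z_for_rate[rate] = loss.calibrate_bandwidth(test_counts, rate).bandwidth_Z

    for model in cfg.models:
        for ri, rate in enumerate(cfg.rates):
            if rate == 0:
                continue  # covered by the baseline row
            for rep in range(cfg.replicates):
                seed = _run_seed(cfg.base_seed, model, ri, rep)
                try:
                    corrupted, report = apply_loss(
                        model, test_counts, test_ev, rate, seed,
                        mean_burst_len=cfg.mean_burst_len,
                        single_mode=cfg.single_mode,
                        congestion_Z=z_for_rate.get(rate))
                    res = fitted.score(corrupted, test_kin)
                except Exception as exc:
                    raise RuntimeError(
                        f"run failed at model={model} rate={rate} "
                        f"replicate={rep} seed={seed}: {exc}") from exc
                rows.append(r2_row(model, rate, rep, seed,
                                   report.overall_rate, res))
                loss_rows.append({
                    "model": model, "loss_rate": rate, "replicate": rep,
                    "seed": seed, "achieved_rate": report.overall_rate,
                    "bins_hit": int(report.mask.sum()),
                    "spikes_lost": int(report.lost_per_bin.sum())})
                if rep == 0:
                    traces[(model, rate)] = res
                logger.info("run %s rate=%g rep=%d achieved=%.4f",
                            model, rate, rep, report.overall_rate)

    r2_table = evaluation.make_r2_table(rows)
    loss_table = pd.DataFrame(
        loss_rows, columns=["model", "loss_rate", "replicate", "seed",
                            "achieved_rate", "bins_hit", "spikes_lost"])
    curves = evaluation.degradation_curves(r2_table)
    result = ExperimentResult(r2_table=r2_table, loss_table=loss_table,
                              baseline=baseline, traces=traces, curves=curves,
                              config_hash=cfg.config_hash())
    if cfg.out_dir:
        result.write(cfg.out_dir)
    return result


def reconstruct_trace(result: DecodeResult, dimension: str | int,
                      bin_width_s: float = 0.128, t0: float = 0.0) -> pd.DataFrame:
    """Aligned (time, actual, predicted) series for one kinematic dimension."""
    if isinstance(dimension, str):
        if dimension not in STATE_LABELS:
            raise ValueError(f"dimension must be one of {STATE_LABELS}")
        d = STATE_LABELS.index(dimension)
    else:
        d = int(dimension)
        if not 0 <= d < 6:
            raise ValueError("dimension index must be in [0, 6)")
    n = result.actual.shape[0]
    return pd.DataFrame({
        "time": t0 + np.arange(n) * bin_width_s,
        "actual": result.actual[:, d],
        "predicted": result.predicted[:, d],
    })
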