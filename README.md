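# spikeloss

Packet-loss robustness analysis for spike-count neural decoding.

In wireless brain–computer interfaces, spike data stream from the
recording headstage to the decoder over a lossy channel. `spikeloss`
quantifies what that loss does to decoding: it generates (or ingests)
binned spike-count data aligned to 2-D reach kinematics, corrupts the
transmitted counts with four distinct packet-loss channel models, decodes
the corrupted stream, and measures the degradation per kinematic
dimension.

## The models

Data are an `N × C` count matrix `A` (`N` time bins of width Δ = 128 ms,
`C` units; `A_ij` = spikes of unit `j` in bin `i`) paired with a 6-D
kinematic state (position, velocity, acceleration in `x` and `y`).

Corruption transforms `A → A′` plus a per-bin loss accounting:

- **Congestion** — a bandwidth cap `Z` packets/bin: in any bin whose total
  `X_i = Σ_j A_ij` exceeds `Z`, only the `Z` earliest spikes survive.
  Controlled by `Z`; `calibrate_bandwidth` finds the `Z` matching a target
  loss rate.
- **Single loss** — scattered loss of individual spikes: `L` random
  decrements of positive entries (`L = round(p·N·C)`, or `round(p·ΣA)` in
  spike-fraction mode).
- **Full loss** — scattered loss of whole bins: `L = round(p·N)` random
  rows zeroed.
- **Burst loss** — a Gilbert–Elliott two-state Markov channel with
  transition probabilities `p = P(Good→Bad)` and `q = P(Bad→Good)`;
  bins visited in the Bad state lose their spikes, giving temporally
  clustered loss with stationary rate `P_loss = p/(p+q) = 1 − q/(p+q)`
  and mean burst length `1/q`.

Decoding uses a Kalman filter over the 6-D state
(`x_{t+1} = F x_t + w`, `y_t = H x_t + v`; F, H by least squares on a
clean 320-s training split), exposed statsmodels-style as
`KalmanDecoder(...).fit() → results` with `decode`, `score` and
`summary()`. A registry slot allows plugging other decoders (e.g. a
recurrent exponential-family harmonium) behind the same interface.
Quality is the per-dimension coefficient of determination
`R² = 1 − ⟨(x−x̂)²⟩ / ⟨(x−⟨x⟩)²⟩`, with one-way ANOVA for comparisons
across loss conditions.

## Worked example

```python
from spikeloss import ExperimentConfig, ReachConfig, run_experiment

cfg = ExperimentConfig(
    reach=ReachConfig(session_length_s=384.1),   # 3,000 bins of 128 ms
    n_units=128,                                 # scaled-down population
    models=("full", "burst"),
    rates=(0.0, 0.02, 0.05, 0.10),
    replicates=5,
    base_seed=1,
)
result = run_experiment(cfg)

curves = result.curves
print(curves[curves.dimension.isin(["pos_x", "acc_x"])].to_string(index=False))
print("baseline R^2:", result.baseline.r2.round(3))
```

prints

```
model  loss_rate dimension  mean    sd  n
burst      0.020     acc_x 0.885 0.004  5
burst      0.020     pos_x 0.963 0.006  5
burst      0.050     acc_x 0.866 0.011  5
burst      0.050     pos_x 0.956 0.007  5
burst      0.100     acc_x 0.800 0.037  5
burst      0.100     pos_x 0.929 0.015  5
 full      0.020     acc_x 0.879 0.003  5
 full      0.020     pos_x 0.964 0.003  5
 full      0.050     acc_x 0.863 0.015  5
 full      0.050     pos_x 0.955 0.011  5
 full      0.100     acc_x 0.820 0.021  5
 full      0.100     pos_x 0.939 0.005  5
 none      0.000     acc_x 0.888 0.000  1
 none      0.000     pos_x 0.969 0.000  1

baseline R^2: [0.969 0.978 0.943 0.95  0.888 0.911]
```

Reading it: the `none` rows are the clean-transmission baseline. At 2%
loss both models barely move any dimension (differences within ~0.01 of
baseline); by 10% loss, acceleration R² has dropped from 0.888 to 0.800
under burst loss while position only falls from 0.969 to 0.929 — bursty,
consecutive loss hurts the fast kinematic derivatives most, and the
decline steepens with rate.

A thin CLI wraps the same stages:

```bash
spikeloss simulate session.h5 --seed 4
spikeloss corrupt session.h5 corrupted.h5 --model burst --rate 0.05
spikeloss decode session.h5 predictions.csv
spikeloss evaluate predictions.csv
spikeloss run-all --seed 5 --out sweep_out   # full sweep, tables + figures
```

## Layout

- `spikeloss.synthetic` — minimum-jerk grid-reach kinematics and
  rectified-linear Poisson spike generation
- `spikeloss.ingest` — channel×type event reshaping, binning, session reader
- `spikeloss.loss` — the four loss models, calibration, loss accounting
- `spikeloss.kalman` — the Kalman decoder model/results and decoder registry
- `spikeloss.evaluation` — R², one-way ANOVA, degradation curves
- `spikeloss.experiment` — sweep orchestration; `spikeloss.cli` — CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
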