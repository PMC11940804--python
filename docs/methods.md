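# Methods

This note documents the models implemented in `spikeloss`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter.

## Synthetic sessions

**Kinematics.** A session is a sequence of self-paced point-to-point
reaches between targets drawn uniformly from a square grid (default 8×8,
5 cm spacing), mimicking a continuous grid-reaching task. Each cycle is a
0.2 s hold followed by a 0.8 s minimum-jerk reach — the quintic
`x(s) = x₀ + (x₁−x₀)(10s³ − 15s⁴ + 6s⁵)`, which is smooth, has zero
velocity and acceleration at both endpoints, and is the standard
closed-form model for primate point-to-point reaching. Position is
sampled at bin centres (Δ = 128 ms, the binning the whole analysis uses);
velocity and acceleration are central finite differences of the sampled
position, so the three blocks of the 6-D state (pos, vel, acc in x, y)
are discretely consistent by construction. Immediate target repeats are
resampled so every reach moves.

**Spikes.** Counts are conditionally Poisson with a rectified linear
rate: `count_ij ~ Poisson(max(0, b_j + H_j · x_i))`. The linear-in-state
mean is the tuning structure the downstream linear decoder assumes;
rectification keeps the Poisson rate valid where the linear predictor
would go negative (~5–10% of bin×unit combinations at the defaults).
Each counted spike is then placed at an i.i.d. uniform time inside its
bin, giving the congestion model a within-bin arrival order; re-binning
the events reproduces the count matrix exactly.

**Tuning defaults (free parameters).** Real per-unit tuning coefficients
are not published for the emulated recordings, so they are free
parameters of the generator: baseline `b = 1` spike/bin/unit (0.5–2 is
the plausible band for sorted cortical units at 128 ms bins) and
Gaussian random gains normalised per kinematic dimension so that one
standard deviation of each dimension modulates the expected count by
0.3·b — a tuning depth typical of motor-cortical units, giving a mean
count of ~1.04 spikes/bin and a population informative about all six
dimensions. These were fixed once, as the generator's definition of a
realistic session, and are exposed as `TuningModel.random(baseline=…,
modulation=…)`.

**What the generator does not emulate.** No waveforms, no spike sorting
errors, no electrode geometry, no non-Poisson count dispersion, no
nonstationarity across a session, and identical tuning depth statistics
across units. Passing tests therefore demonstrate the pipeline's
behaviour under its own assumptions (linear tuning, stationary Poisson
noise); they do not certify effect sizes on real recordings, where
decoders are weaker and loss effects can be larger.

## Loss models

All four models transform a count matrix and return a `LossReport`
(per-bin original/lost packet counts, bin-level mask, overall rate);
conservation `Σoriginal − Σlost = Σcorrupted` holds for every model, and
every stochastic model is reproducible under a fixed seed.

- **Congestion.** Row totals `X_i` above the bandwidth `Z` lose their
  latest spikes: all spikes of a bin are ordered by arrival time (ties
  broken by ascending unit index — the generator's continuous times make
  ties measure-zero, but file-ingested data can tie) and only the first
  `Z` survive, so corrupted row sums are exactly `min(X_i, Z)`.
  `calibrate_bandwidth` finds the integer `Z` whose loss rate
  `Σ max(X_i−Z, 0)/ΣX` is closest to a target by bisection (the rate is
  non-increasing in `Z`).
- **Full loss.** Exactly `L = round(p·N)` distinct rows, uniform without
  replacement, are zeroed. Rounding is half-away-from-zero here and
  everywhere a budget is rounded.
- **Single loss.** `L` single-spike decrements. The default (literal)
  budget is `L = p·N·C` with each decrement hitting a uniformly random
  currently-positive entry; this makes the achieved spike-loss fraction
  depend on the mean count per cell, so a `spike_fraction` mode is also
  provided in which `L = p·ΣA` and spikes are removed uniformly over the
  spike population (multivariate hypergeometric), achieving exactly `p`.
  If `L` exceeds the spikes available the model refuses, naming the
  shortfall.
- **Burst (Gilbert–Elliott).** A two-state Markov chain over bins; bin 0
  carries the initial Good state and transitions apply per bin
  (`P(G→B) = p`, `P(B→G) = q`). Bad bins lose `loss_fraction_in_bad` of
  their spikes — 1.0 (the whole row) by default, since the loss
  intervals this model represents are total dropouts; partial severity
  removes a spike-uniform `round(f·X_i)` subset. `ge_params_from`
  inverts the stationary relations (`P_loss = p/(p+q)`, mean burst
  `1/q`): `q = 1/mean_burst_len`, `p = P_loss·q/(1−P_loss)`, exact to
  machine precision on the round trip.

## Decoder

The shipped decoder is a Kalman filter, presented model/results-style:
`KalmanDecoder(train_counts, train_kin).fit()` estimates
`x_{t+1} = F x_t + w`, `y_t = H x_t + v` on centred data — `F` and `H` by
least squares (relative ridge `1e-8` guards rank deficiency), `Q`/`R` as
residual covariances with a small diagonal floor so `R` stays invertible
when units are silent or near-collinear (important when `C` approaches
the number of training bins). The initial state is the training mean with
the training state covariance. Filtering uses the information-form
update (`P⁻¹_post = P⁻¹_pred + HᵀR⁻¹H` after one Cholesky factorisation
of `R`), algebraically identical to the innovation form but `O(C)` per
bin instead of `O(C³)`. An optional square-root count transform
(variance stabilisation) is off by default. The decoder registry lets an
external decoder — e.g. a recurrent exponential-family harmonium, which
this package deliberately does not reimplement — be plugged in behind
the same fit/decode surface; conclusions here are stated for the Kalman
reference decoder and the ordering (not magnitude) of effects may differ
across decoders.

## Evaluation

`R² = 1 − ⟨(x−x̂)²⟩/⟨(x−⟨x⟩)²⟩` per dimension. This quantity is negative
whenever the predictor underperforms the observed mean; although the
coefficient of determination is often described as ranging over [0, 1],
that only holds for in-sample regression fits, and out-of-sample decoding
can and does go below 0. Negative values are reported as-is (`clip=True`
clamps them for comparison with the conventional description). Zero
variance in the observed series is an error, not a silent 0 or 1.

One-way ANOVA (between/within mean squares, F with `(k−1, n−k)` df)
compares R² replicates across loss rates within a model, or across
models at a fixed rate; both groupings are meaningful and callers choose.
p-values are reported uncorrected — sweeps that test many
dimension×model cells should apply their own multiplicity control.

## Experiment design

The sweep fits the decoder once on the clean head of the session
(default 320 s of training data) and corrupts only the test segment,
replicating transmission loss to a decoder calibrated under good
conditions; training-set corruption is a different question deliberately
out of scope. The nominal rate grid `{0, 0.5, 1, 2, 3, 5, 7, 10}%` spans
the loss range reported for practical wireless recording systems;
congestion is swept over bandwidths calibrated per rate on the clean
test matrix so all models share an x-axis. Per-run seeds derive from
`SeedSequence([base_seed, model, rate, replicate])`, making the sweep
order-independent and byte-reproducible; each run's seed and achieved
loss rate are stored in the output tables.

## Problem sizes

The defaults mirror the emulated recordings: 576 units (192 channels × 3
spike types), 5,000 bins (640 s). The test suite and the pipeline checks
run a scaled-down population of 128 units × 3,000 bins with 20
replicates, chosen because the qualitative behaviour under study — the
ordering of dimension sensitivities under bursty loss — is stable for
populations of ≥128 units but becomes erratic for very small populations
(at ~64 units, the state the filter infers from a zeroed bin has large
random position components that dominate the comparison). Loss-model
calibration checks run at the full 5,000 × 576 scale, where they take
seconds.

## Known limitations

- Degradation magnitudes are specific to the Kalman reference decoder
  and the synthetic tuning model; only the qualitative structure
  (burst/full loss worse than scattered single-spike loss, fast
  derivatives most affected, ≤2% loss nearly harmless) is expected to
  transfer.
- The corrupted stream is decoded as-is: the decoder is not told which
  bins were lost, and no imputation/retransmission countermeasures are
  modelled.
- The Gilbert–Elliott chain operates at bin resolution (128 ms); bursts
  shorter than a bin are not representable.
- The session reader expects the deposited HDF5 cell-array layout and is
  exercised against synthetic files only.
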