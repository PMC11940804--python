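"""Reference Kalman-filter decoder mapping spike counts to 6-D kinematics.

The decoder follows the statsmodels model/results convention:
:class:`KalmanDecoder` is built from training data, ``fit()`` estimates the
linear-Gaussian state-space parameters by least squares, and the returned
:class:`KalmanDecoderResults` runs the filter on (possibly corrupted) test
counts, scores predictions, and prints a ``summary()``.

Model:  ``x_{t+1} = F x_t + w_t``,  ``y_t = H x_t + v_t`` with
``w ~ N(0, Q)``, ``v ~ N(0, R)``; ``x`` is the centred 6-D kinematic
state and ``y`` the centred (optionally square-root transformed) count
vector.  F and H are ordinary least-squares fits on the training split;
Q and R are the residual covariances, ridge-regularised with a diagonal
floor so the filter stays well-posed when units are silent or collinear.

A registry maps decoder names to factories so alternative decoders (e.g.
a recurrent exponential-family harmonium, the decoder this package's
analysis was designed around but does not reimplement) can be plugged in
behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import h5py
import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .ingest import CountMatrix
from .synthetic import Kinematics, STATE_LABELS

__all__ = [
    "DecoderSpec",
    "DecodeResult",
    "KalmanDecoder",
    "KalmanDecoderResults",
    "register_decoder",
    "get_decoder_factory",
]


@dataclass
class DecoderSpec:
    """Named decoder configuration used by the experiment layer.

    ``train_seconds`` is the length of the training split (default 320 s,
    the training-time setting the analysis standardises on); everything
    after it is test data, so the two index ranges are disjoint by
    construction.
    """

    name: str = "kalman"
    train_seconds: float = 320.0
    hyperparams: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.train_seconds <= 0:
            raise ValueError("train_seconds must be positive")


@dataclass
class DecodeResult:
    """Predicted vs actual kinematics with per-dimension R^2."""

    predicted: np.ndarray
    actual: np.ndarray
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.actual = np.asarray(self.actual, dtype=float)
        if self.predicted.shape != self.actual.shape:
            raise ValueError("predicted and actual must have the same shape")
        self.r2 = np.asarray(self.r2, dtype=float)


def _ols(X: np.ndarray, Y: np.ndarray, ridge: float) -> np.ndarray:
    """Ridge-stabilised least squares solving ``Y ~ X B``; returns B.T."""
    G = X.T @ X
    lam = ridge * max(np.trace(G) / max(X.shape[1], 1), 1.0)
    G = G + lam * np.eye(X.shape[1])
    try:
        B = np.linalg.solve(G, X.T @ Y)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise np.linalg.LinAlgError(
            "design matrix singular even after ridge regularisation") from exc
    return B.T


class KalmanDecoder:
    """Linear-Gaussian decoder model built from a training split.

    Parameters
    ----------
    train_counts : CountMatrix
        Training spike counts (N_train x C), never corrupted.
    train_kin : Kinematics
        Matching kinematic states (N_train x 6).
    sqrt_transform : bool
        Apply ``sqrt(y)`` to counts before fitting/filtering
        (variance stabilisation for Poisson counts); default off.
    ridge : float
        Relative ridge strength for the F and H regressions.
    noise_floor : float
        Diagonal floor added to Q and R.
    """

    def __init__(self, train_counts: CountMatrix, train_kin: Kinematics, *,
                 sqrt_transform: bool = False, ridge: float = 1e-8,
                 noise_floor: float = 1e-9):
        if train_counts.n_bins != train_kin.n_bins:
            raise ValueError("training counts and kinematics lengths differ")
        if train_counts.n_bins < 2:
            raise ValueError("need at least 2 training bins")
        self.train_counts = train_counts
        self.train_kin = train_kin
        self.sqrt_transform = bool(sqrt_transform)
        self.ridge = float(ridge)
        self.noise_floor = float(noise_floor)

    @classmethod
    def from_spec(cls, spec: DecoderSpec, train_counts: CountMatrix,
                  train_kin: Kinematics) -> "KalmanDecoder":
        return cls(train_counts, train_kin, **spec.hyperparams)

    def _observations(self, counts: CountMatrix) -> np.ndarray:
        y = counts.counts.astype(float)
        return np.sqrt(y) if self.sqrt_transform else y

    def fit(self) -> "KalmanDecoderResults":
        """Estimate F, H, Q, R and return a results object."""
        X = self.train_kin.states
        Y = self._observations(self.train_counts)
        x_mean = X.mean(axis=0)
        y_mean = Y.mean(axis=0)
        Xc = X - x_mean
        Yc = Y - y_mean
        n = Xc.shape[0]

        F = _ols(Xc[:-1], Xc[1:], self.ridge)
        w = Xc[1:] - Xc[:-1] @ F.T
        Q = (w.T @ w) / max(n - 1, 1) + self.noise_floor * np.eye(6)

        H = _ols(Xc, Yc, self.ridge)
        v = Yc - Xc @ H.T
        C = Yc.shape[1]
        R = (v.T @ v) / n
        # shrink off-diagonals slightly so R stays invertible when C ~ n
        R = R + (self.noise_floor + 1e-6 * np.trace(R) / max(C, 1)) * np.eye(C)

        P0 = (Xc.T @ Xc) / n + self.noise_floor * np.eye(6)
        return KalmanDecoderResults(model=self, F=F, H=H, Q=Q, R=R,
                                    x_mean=x_mean, y_mean=y_mean, P0=P0)


@dataclass
class KalmanDecoderResults:
    """Fitted decoder: filter recursion, scoring, persistence."""

    model: KalmanDecoder | None
    F: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    P0: np.ndarray
    sqrt_transform: bool = False

    def __post_init__(self) -> None:
        if self.model is not None:
            self.sqrt_transform = self.model.sqrt_transform

    @property
    def n_units(self) -> int:
        return self.H.shape[0]

    def decode(self, test_counts: CountMatrix) -> np.ndarray:
        """Run the Kalman filter over test bins; returns N_test x 6 states.

        The update uses the information form: with a single Cholesky
        factorisation of R, each bin needs only 6x6 solves
        (``P_post^-1 = P_pred^-1 + H' R^-1 H``), which is algebraically
        identical to the innovation-covariance form but stays cheap for
        populations of hundreds of units.  Deterministic given the fitted
        parameters and inputs.
        """
        if test_counts.n_units != self.n_units:
            raise ValueError(
                f"decoder fitted for {self.n_units} units, got "
                f"{test_counts.n_units}")
        Y = test_counts.counts.astype(float)
        if self.sqrt_transform:
            Y = np.sqrt(Y)
        Yc = Y - self.y_mean
        F, H, Q = self.F, self.H, self.Q
        cfR = cho_factor(self.R, lower=True, check_finite=False)
        RinvH = cho_solve(cfR, H, check_finite=False)         # C x 6
        HtRinvH = H.T @ RinvH                                 # 6 x 6
        info_obs = Yc @ RinvH                                 # N x 6: H'R^-1 y
        x = np.zeros(6)
        P = self.P0.copy()
        I6 = np.eye(6)
        out = np.empty((Yc.shape[0], 6))
        for t in range(Yc.shape[0]):
            x = F @ x
            P = F @ P @ F.T + Q
            Pinv = np.linalg.solve(P, I6)
            P = np.linalg.solve(Pinv + HtRinvH, I6)
            P = 0.5 * (P + P.T)
            x = P @ (Pinv @ x + info_obs[t])
            out[t] = x
        return out + self.x_mean

    def score(self, test_counts: CountMatrix, test_kin: Kinematics) -> DecodeResult:
        """Decode and score against held-out kinematics (R^2 per dimension)."""
        from .evaluation import r2_by_dimension  # R^2 lives in evaluation

        pred = self.decode(test_counts)
        r2 = r2_by_dimension(test_kin.states, pred)
        return DecodeResult(predicted=pred, actual=test_kin.states, r2=r2)

    def summary(self) -> str:
        """Plain-text summary of the fitted state-space model."""
        eig = np.abs(np.linalg.eigvals(self.F))
        lines = [
            "Kalman decoder (linear-Gaussian state space)",
            "=" * 46,
            f"units (C):            {self.n_units}",
            f"state dims:           6 ({', '.join(STATE_LABELS)})",
            f"sqrt count transform: {self.sqrt_transform}",
            f"|eig(F)| range:       [{eig.min():.4f}, {eig.max():.4f}]",
            f"tr(Q):                {np.trace(self.Q):.4g}",
            f"tr(R):                {np.trace(self.R):.4g}",
            f"mean count (fit):     {float(np.mean(self.y_mean)):.3f} spikes/bin",
        ]
        return "\n".join(lines)

    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            for name in ("F", "H", "Q", "R", "x_mean", "y_mean", "P0"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["sqrt_transform"] = self.sqrt_transform

    @classmethod
    def from_hdf5(cls, path: str) -> "KalmanDecoderResults":
        with h5py.File(path, "r") as f:
            arrs = {name: np.asarray(f[name])
                    for name in ("F", "H", "Q", "R", "x_mean", "y_mean", "P0")}
            sqrt = bool(f.attrs.get("sqrt_transform", False))
        return cls(model=None, sqrt_transform=sqrt, **arrs)


# -- decoder registry ---------------------------------------------------------

_REGISTRY: dict[str, Callable[[DecoderSpec, CountMatrix, Kinematics], Any]] = {}


def register_decoder(name: str,
                     factory: Callable[[DecoderSpec, CountMatrix, Kinematics], Any]) -> None:
    """Register a decoder factory; it must return an object with
    ``fit() -> results`` where results expose ``decode(CountMatrix)``."""
    _REGISTRY[name] = factory


def get_decoder_factory(name: str) -> Callable[[DecoderSpec, CountMatrix, Kinematics], Any]:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown decoder '{name}'; registered: {sorted(_REGISTRY)}") from None


register_decoder("kalman", KalmanDecoder.from_spec)
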