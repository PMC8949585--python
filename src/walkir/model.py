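"""Two-component (fitness-fatigue) impulse-response model of performance.

The Banister systems model treats the exercising subject as a first-order
linear system: the daily training quantity w(t) is the input and predicted
performance p(t) (metres of walking distance) the output.  Each unit of
load raises a *fitness* and a *fatigue* component, each decaying
exponentially with its own time constant::

    p(t) = p0 + k1 * sum_{i<t} w(i) exp(-(t-i)/tau1)
              - k2 * sum_{i<t} w(i) exp(-(t-i)/tau2)

where k1, k2 >= 0 are magnitude factors (metres per a.u. of TRIMP) and
tau1, tau2 > 0 are decay time constants in days: after tau days a
component has fallen to e^-1 ~ 37% of its initial value.  A day's training
influences performance from the *following* day onward (the sum runs over
i < t), the standard discretisation for daily loads.

Predicted performance is baseline plus fitness minus fatigue.  Because
fatigue typically decays faster (tau2 < tau1), performance keeps rising
for a short while after training stops, then decays back toward baseline —
the detraining decay quantified by :func:`decay_to_baseline`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exceptions import SpanError, UndefinedDecayError
from .trimp import TrimpSeries

__all__ = [
    "IRParameters",
    "PerformanceTrajectory",
    "impulse_response",
    "predict_performance",
    "decay_to_baseline",
]


@dataclass(frozen=True)
class IRParameters:
    """Subject-level model parameters.

    p0 : baseline performance (m); k1, k2 : fitness/fatigue magnitudes
    (a.u.); tau1, tau2 : decay time constants (days).
    """

    p0: float
    k1: float
    k2: float
    tau1: float
    tau2: float

    def __post_init__(self) -> None:
        if self.p0 < 0:
            raise ValueError(f"p0 must be >= 0, got {self.p0}")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("magnitude factors k1, k2 must be >= 0")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("decay constants tau1, tau2 must be > 0 days")


@dataclass
class PerformanceTrajectory:
    """Daily model output: days 0..horizon with component decomposition."""

    days: np.ndarray
    predicted: np.ndarray
    fitness: np.ndarray
    fatigue: np.ndarray

    def to_frame(self, trimps: TrimpSeries | None = None) -> pd.DataFrame:
        """Tabulate day, trimp, fitness, fatigue, predicted (CSV export layout)."""
        w = np.zeros(len(self.days))
        if trimps is not None:
            n = min(len(trimps), len(w))
            w[:n] = trimps.values[:n]
        return pd.DataFrame(
            {
                "day": self.days,
                "trimp": w,
                "fitness": self.fitness,
                "fatigue": self.fatigue,
                "predicted": self.predicted,
            }
        )


def impulse_response(k: float, tau: float, t: float | np.ndarray) -> float | np.ndarray:
    """First-order impulse response g(t) = k * exp(-t / tau).

    At t = tau the response has decayed to k/e (about 37% of its initial
    value). Negative t raises ``ValueError``.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0 days, got {tau}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0 days")
    out = k * np.exp(-t / tau)
    return float(out) if out.ndim == 0 else out


def _exp_accumulate(w: np.ndarray, tau: float) -> np.ndarray:
    """s(t) = sum_{i<t} w(i) a^(t-i), a = exp(-1/tau), via a recursive filter."""
    a = np.exp(-1.0 / tau)
    # s(t) = a * s(t-1) + a * w(t-1)  ->  IIR filter b=[0, a], a=[1, -a]
    return lfilter([0.0, a], [1.0, -a], w)


def predict_performance(
    params: IRParameters, trimps: TrimpSeries, horizon: int | None = None
) -> PerformanceTrajectory:
    """Convolve the TRIMP series with the fitness and fatigue responses.

    Returns the trajectory for integer days 0..``horizon`` inclusive;
    ``horizon`` defaults to the series length and must not be shorter.
    Days beyond the series carry w = 0 (detraining extension).
    """
    n = len(trimps)
    if horizon is None:
        horizon = n
    if horizon < n:
        raise SpanError(f"horizon {horizon} shorter than TRIMP series ({n} days)")
    w = np.zeros(horizon + 1)
    w[:n] = trimps.values
    fitness = params.k1 * _exp_accumulate(w, params.tau1)
    fatigue = params.k2 * _exp_accumulate(w, params.tau2)
    predicted = params.p0 + fitness - fatigue
    return PerformanceTrajectory(
        days=np.arange(horizon + 1), predicted=predicted, fitness=fitness, fatigue=fatigue
    )


def predict_at_days(
    params: IRParameters, trimps: TrimpSeries, days: np.ndarray
) -> np.ndarray:
    """Predicted performance at specific integer day indices."""
    days = np.asarray(days, dtype=int)
    if np.any(days < 0):
        raise SpanError("day indices must be >= 0")
    traj = predict_performance(params, trimps, horizon=max(int(days.max()), len(trimps)))
    return traj.predicted[days]


def decay_to_baseline(
    params: IRParameters,
    trimps: TrimpSeries,
    threshold_fraction: float = 0.05,
    max_days: int = 3650,
) -> float:
    """Weeks after training cessation until the gain is essentially gone.

    Simulates detraining (w = 0 after the last training day) and returns
    the time, in weeks from cessation, at which the residual gain
    p(t) - p0 first falls to ``threshold_fraction`` of the peak
    post-training gain.  Exponential decay is asymptotic, so an exact
    return to baseline never occurs; the default 5% threshold
    operationalises "return to baseline".  Raises
    :class:`UndefinedDecayError` when training produced no positive gain.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    nonzero = np.nonzero(trimps.values > 0)[0]
    if len(nonzero) == 0:
        raise UndefinedDecayError("TRIMP series contains no training")
    cessation = int(nonzero[-1]) + 1  # first detraining day
    traj = predict_performance(params, trimps, horizon=cessation + max_days)
    gain = traj.predicted[cessation:] - params.p0
    if gain[0] <= 0:
        raise UndefinedDecayError("no positive training-induced gain at cessation")
    peak_idx = int(np.argmax(gain))
    peak = gain[peak_idx]
    below = np.nonzero(gain[peak_idx:] <= threshold_fraction * peak)[0]
    if len(below) == 0:
        raise UndefinedDecayError(
            f"gain did not decay below threshold within {max_days} days"
        )
    return (peak_idx + int(below[0])) / 7.0
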