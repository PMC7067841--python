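"""First-order kinetic fits of incorporation / wash-out time courses.

The model is the three-parameter mono-exponential relaxation

    y(t) = y_inf + (y0 - y_inf) * exp(-k * t)

which covers both rising (incorporation) and decaying (wash-out) courses
by the sign of (y0 - y_inf).  The reported half-time is ln(2)/k: the time
at which the remaining excess |y(t) - y_inf| has halved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["TimeCourse", "KineticFit", "fit_first_order", "half_time", "read_time_course"]

K_BOUNDS = (1e-6, 1e3)  # per hour


@dataclass
class TimeCourse:
    """A measured statistic vs time (hours)."""

    times: np.ndarray
    values: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size < 4:
            raise ValueError("need at least 4 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("times must be >= 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


@dataclass
class KineticFit:
    """Fitted first-order model."""

    y0: float
    y_inf: float
    k: float  # per hour
    rss: float
    converged: bool

    @property
    def half_time(self) -> float:
        return math.log(2.0) / self.k

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.y_inf + (self.y0 - self.y_inf) * np.exp(-self.k * np.asarray(t, dtype=float))


def _initial_k(t: np.ndarray, y: np.ndarray) -> float:
    """k guess from the time of closest approach to the midpoint value."""
    mid = 0.5 * (y[0] + y[-1])
    i = int(np.argmin(np.abs(y - mid)))
    t_half = t[i] if t[i] > 0 else (t[1] if t[1] > 0 else 1.0)
    return float(np.clip(math.log(2.0) / t_half, *K_BOUNDS))


def fit_first_order(tc: TimeCourse) -> KineticFit:
    """Nonlinear least-squares fit of the mono-exponential model.

    Ordinary (unweighted) least squares over (y0, y_inf, k) with k
    constrained positive.  Optimizer failure sets ``converged=False``
    rather than raising.  Deterministic for a fixed input.
    """
    t, y = tc.times, tc.values
    if np.allclose(y, y[0]):
        raise ValueError("all values equal: rate is unidentifiable")

    span = float(y.max() - y.min())
    x0 = np.array([y[0], y[-1], _initial_k(t, y)])

    def resid(p):
        y0, yinf, k = p
        return yinf + (y0 - yinf) * np.exp(-k * t) - y

    lo = [y.min() - 10 * span, y.min() - 10 * span, K_BOUNDS[0]]
    hi = [y.max() + 10 * span, y.max() + 10 * span, K_BOUNDS[1]]
    try:
        sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        converged = bool(sol.success)
        y0, yinf, k = sol.x
        rss = float(np.sum(sol.fun**2))
    except Exception:
        converged = False
        y0, yinf, k = x0
        rss = float(np.sum(resid(x0) ** 2))
    return KineticFit(float(y0), float(yinf), float(k), rss, converged)


def half_time(fit: KineticFit) -> float:
    """ln(2)/k of a converged fit (hours)."""
    if not fit.converged:
        raise ValueError("fit did not converge; half-time unreliable")
    return fit.half_time


def read_time_course(path: str | Path, condition: str = "") -> TimeCourse:
    """Read a time-course CSV with columns ``time_h,value[,replicate]``.

    Replicate readings at the same time point are averaged; with balanced
    replication the least-squares fit of the means equals the pooled fit.
    """
    df = pd.read_csv(path)
    if not {"time_h", "value"} <= set(df.columns):
        raise ValueError("time-course CSV needs columns time_h,value")
    df = df.groupby("time_h", as_index=False)["value"].mean().sort_values("time_h")
    return TimeCourse(
        df["time_h"].to_numpy(dtype=float),
        df["value"].to_numpy(dtype=float),
        condition,
    )
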