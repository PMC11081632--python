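"""Logistic growth fitting and the relative knockdown proliferation effect.

Live-cell imagers report per-well confluency (percent of the field covered
by cells) every few hours. Proliferation rate is obtained by fitting the
logistic growth model

    N(t) = K * N0 / (N0 + (K - N0) * exp(-r * t))

where ``r`` (1/h) is the intrinsic growth rate, ``K`` the carrying
capacity (% confluency) and ``N0`` the initial confluency. The effect of
an shRNA knockdown relative to a non-targeting control is

    effect = (r_target - r_control) / r_control

so 0 means no effect, -1 complete proliferation arrest and positive values
growth activation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import GIScreenError, InsufficientDataError

logger = logging.getLogger("giscreen")

__all__ = [
    "GrowthCurve",
    "LogisticFit",
    "RelativeEffect",
    "logistic_value",
    "fit_logistic",
    "relative_effect",
]

MIN_POINTS = 5


@dataclass
class GrowthCurve:
    """One replicate's confluency time series."""

    times: np.ndarray  # hours, strictly increasing
    confluency: np.ndarray  # percent, in [0, 100]
    cell_line: str = ""
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.confluency = np.asarray(self.confluency, dtype=float)
        if self.times.shape != self.confluency.shape:
            raise GIScreenError("times and confluency must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise GIScreenError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise GIScreenError("times must be non-negative")
        if np.any((self.confluency < 0) | (self.confluency > 100)):
            raise GIScreenError("confluency must lie in [0, 100] percent")


@dataclass
class LogisticFit:
    r: float  # growth rate, 1/h
    K: float  # carrying capacity, % confluency
    N0: float  # initial confluency, %
    rss: float
    converged: bool
    message: str = ""


@dataclass
class RelativeEffect:
    target_condition: str
    mean_effect: float
    sd_effect: float
    per_replicate: list[float]


def logistic_value(
    t: float | np.ndarray, r: float, K: float, N0: float
) -> float | np.ndarray:
    """Evaluate the logistic growth curve N(t) = K*N0/(N0+(K-N0)e^{-rt})."""
    if K <= 0 or N0 <= 0:
        raise ValueError(f"K and N0 must be positive, got K={K}, N0={N0}")
    t = np.asarray(t, dtype=float)
    out = K * N0 / (N0 + (K - N0) * np.exp(-r * t))
    return float(out) if out.ndim == 0 else out


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    n0 = max(float(y[0]), 0.1)
    k = max(1.05 * float(y.max()), n0 + 1.0)
    half = max(2, t.size // 2)
    logy = np.log(np.clip(y[:half], 0.1, None))
    r = float(np.polyfit(t[:half], logy, 1)[0])
    r = float(np.clip(r, -0.99, 0.99))
    if r == 0.0:
        r = 1e-3
    return r, k, n0


def fit_logistic(curve: GrowthCurve) -> LogisticFit:
    """Least-squares logistic fit of a confluency time series.

    Needs at least five time points. A flat (degenerate) series returns a
    non-converged fit with a diagnostic message rather than raising. All
    points are weighted equally. Bounds: r in [-1, 1] 1/h (negative rates
    are flagged by sign, not rejected), K in (0, 200].
    """
    t = curve.times
    y = curve.confluency
    if t.size < MIN_POINTS:
        raise InsufficientDataError(
            f"need >= {MIN_POINTS} time points for a logistic fit, got {t.size}"
        )
    if float(np.ptp(y)) < 1e-9:
        return LogisticFit(
            r=float("nan"),
            K=float("nan"),
            N0=float("nan"),
            rss=0.0,
            converged=False,
            message="degenerate series: confluency is constant",
        )
    p0 = _initial_guess(t, y)
    bounds = ([-1.0, 1e-6, 1e-6], [1.0, 200.0, 200.0])
    try:
        popt, _ = curve_fit(
            logistic_value, t, y, p0=p0, bounds=bounds, maxfev=10000
        )
    except RuntimeError as exc:
        return LogisticFit(
            r=float("nan"),
            K=float("nan"),
            N0=float("nan"),
            rss=float("nan"),
            converged=False,
            message=f"optimizer failed: {exc}",
        )
    r, k, n0 = (float(v) for v in popt)
    rss = float(np.sum((logistic_value(t, r, k, n0) - y) ** 2))
    converged = k > n0 > 0
    msg = "" if converged else "fit violates K > N0 > 0"
    if r < 0:
        msg = (msg + "; " if msg else "") + "negative growth rate"
    return LogisticFit(r=r, K=k, N0=n0, rss=rss, converged=converged, message=msg)


def relative_effect(
    fits_target: Sequence[LogisticFit],
    fits_control: Sequence[LogisticFit],
    target_condition: str = "",
) -> RelativeEffect:
    """Relative proliferation effect of a knockdown versus its control.

    Per-replicate effects are computed against the mean control rate from
    the same cell line: ``(r_i - mean(r_control)) / mean(r_control)``.
    Only converged fits contribute.
    """
    r_target = [f.r for f in fits_target if f.converged]
    r_control = [f.r for f in fits_control if f.converged]
    if not r_target or not r_control:
        raise InsufficientDataError("need >= 1 converged fit per group")
    r_ctrl_mean = float(np.mean(r_control))
    if r_ctrl_mean == 0.0:
        raise ZeroDivisionError("mean control growth rate is zero")
    effects = [(r - r_ctrl_mean) / r_ctrl_mean for r in r_target]
    sd = float(np.std(effects, ddof=1)) if len(effects) > 1 else 0.0
    return RelativeEffect(
        target_condition=target_condition,
        mean_effect=float(np.mean(effects)),
        sd_effect=sd,
        per_replicate=[float(e) for e in effects],
    )
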