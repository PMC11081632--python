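"""Four-parameter logistic dose-response fitting with profile-likelihood CIs.

Viability readouts (e.g. resazurin fluorescence) are first normalized to
the untreated and blank controls, then fitted with the standard 4PL model

    f(c) = bottom + (top - bottom) / (1 + (c / IC50)^hill)

with ``hill > 0`` so the response falls from ``top`` at c=0 toward
``bottom`` at saturating concentration. The IC50 is parameterized on the
log10 scale during fitting. The 95% confidence interval for the IC50 comes
from the likelihood profile with an F-test threshold, which naturally
produces the strongly asymmetric intervals typical of sparse cytotoxicity
designs; symmetric Wald intervals cannot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq, curve_fit

from .errors import DesignError, GIScreenError, NormalizationError

logger = logging.getLogger("giscreen")

__all__ = [
    "DoseResponse",
    "FourPLFit",
    "normalize_viability",
    "fourpl_value",
    "fit_dose_response",
]

MIN_DISTINCT_DOSES = 5
MIN_SPAN_LOG10 = 1.5


@dataclass
class DoseResponse:
    """Normalized viability fractions versus concentration (µM)."""

    concentrations: np.ndarray
    responses: np.ndarray
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise GIScreenError("concentrations and responses must match in length")
        if np.any(self.concentrations < 0):
            raise GIScreenError("concentrations must be non-negative")


@dataclass
class FourPLFit:
    ic50: float  # µM
    hill: float
    top: float
    bottom: float
    ci_low: float  # µM, 95% profile-likelihood bound
    ci_high: float  # µM
    rss: float
    converged: bool
    message: str = ""


def normalize_viability(
    raw_fluorescence: Sequence[float], untreated_mean: float, blank_mean: float
) -> np.ndarray:
    """Map raw fluorescence to viability fractions.

    fraction = (raw - blank) / (untreated - blank); values above 1 are
    legitimate (wells outgrowing the untreated mean) and preserved.
    """
    if untreated_mean <= blank_mean:
        raise NormalizationError(
            f"untreated mean ({untreated_mean}) must exceed blank mean ({blank_mean})"
        )
    raw = np.asarray(raw_fluorescence, dtype=float)
    return (raw - blank_mean) / (untreated_mean - blank_mean)


def fourpl_value(
    c: float | np.ndarray, ic50: float, hill: float, top: float, bottom: float
) -> float | np.ndarray:
    """Evaluate the 4PL curve; c=0 maps exactly to the top asymptote."""
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / ic50) ** hill, 0.0)
    out = bottom + (top - bottom) / (1.0 + ratio)
    return float(out) if out.ndim == 0 else out


def _model_logged(c: np.ndarray, l10_ic50: float, hill: float, top: float, bottom: float) -> np.ndarray:
    return fourpl_value(c, 10.0 ** l10_ic50, hill, top, bottom)


def _check_design(conc: np.ndarray) -> None:
    pos = np.unique(conc[conc > 0])
    if pos.size < MIN_DISTINCT_DOSES:
        raise DesignError(
            f"need >= {MIN_DISTINCT_DOSES} distinct positive concentrations, "
            f"got {pos.size}"
        )
    span = float(np.log10(pos.max() / pos.min()))
    if span < MIN_SPAN_LOG10:
        raise DesignError(
            f"concentrations span {span:.2f} log10 units, "
            f"need >= {MIN_SPAN_LOG10}"
        )


def _profile_rss(
    conc: np.ndarray, resp: np.ndarray, l10: float, p0: Sequence[float]
) -> float:
    """Minimum RSS over (hill, top, bottom) with log10 IC50 held fixed."""

    def model(c: np.ndarray, hill: float, top: float, bottom: float) -> np.ndarray:
        return _model_logged(c, l10, hill, top, bottom)

    try:
        popt, _ = curve_fit(model, conc, resp, p0=p0, maxfev=5000)
    except RuntimeError:
        return float("inf")
    return float(np.sum((model(conc, *popt) - resp) ** 2))


def _profile_ci(
    conc: np.ndarray,
    resp: np.ndarray,
    popt: np.ndarray,
    rss0: float,
    level: float = 0.95,
    max_decades: float = 6.0,
) -> tuple[float, float]:
    n, p = resp.size, 4
    dof = n - p
    if dof <= 0:
        return float("nan"), float("nan")
    fcrit = float(stats.f.ppf(level, 1, dof))
    # Guard against an exactly-zero RSS (noise-free data): the profile is
    # then a spike and the interval collapses onto the estimate.
    floor = max(rss0, 1e-30)
    threshold = floor * (1.0 + fcrit / dof)
    l10_hat = float(popt[0])
    inner_p0 = popt[1:]

    def excess(l10: float) -> float:
        return _profile_rss(conc, resp, l10, inner_p0) - threshold

    bounds = []
    for sign in (-1.0, 1.0):
        step = 0.25
        lo_in = l10_hat
        found = None
        x = l10_hat
        while abs(x - l10_hat) < max_decades:
            x = x + sign * step
            if excess(x) > 0:
                found = x
                break
            lo_in = x
        if found is None:
            bounds.append(l10_hat + sign * max_decades)  # open interval end
            continue
        root = brentq(excess, min(lo_in, found), max(lo_in, found), xtol=1e-4)
        bounds.append(float(root))
    low, high = sorted(bounds)
    return 10.0 ** low, 10.0 ** high


def fit_dose_response(data: DoseResponse, ci_level: float = 0.95) -> FourPLFit:
    """Fit the 4PL model and a profile-likelihood IC50 interval.

    Requires at least five distinct positive concentrations spanning at
    least 1.5 log10 units. Zero-concentration (untreated) points take part
    through the top plateau. A series with no dose-dependent decline is
    returned as non-converged with a diagnostic, not an exception.
    """
    conc = data.concentrations
    resp = data.responses
    _check_design(conc)
    # No-toxicity guard: responses must decline with dose overall.
    pos = conc > 0
    rho = stats.spearmanr(conc[pos], resp[pos]).statistic
    if not (rho < 0):
        return FourPLFit(
            ic50=float("nan"),
            hill=float("nan"),
            top=float("nan"),
            bottom=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            rss=float("nan"),
            converged=False,
            message="no dose-dependent decline in response",
        )
    posc = conc[pos]
    top0 = float(np.mean(resp[conc == conc.min()]))
    bottom0 = float(np.mean(resp[conc == conc.max()]))
    # start the IC50 at the dose whose mean response is nearest the midpoint
    mid = 0.5 * (top0 + bottom0)
    doses = np.unique(posc)
    means = np.array([resp[conc == d].mean() for d in doses])
    l10_0 = float(np.log10(doses[np.argmin(np.abs(means - mid))]))
    p0 = [l10_0, 1.0, top0, bottom0]
    try:
        popt, _ = curve_fit(_model_logged, conc, resp, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        return FourPLFit(
            ic50=float("nan"),
            hill=float("nan"),
            top=float("nan"),
            bottom=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            rss=float("nan"),
            converged=False,
            message=f"optimizer failed: {exc}",
        )
    # Canonical orientation: hill > 0 with top > bottom. The model is
    # invariant under (hill, top, bottom) -> (-hill, bottom, top).
    if popt[1] < 0:
        popt = np.array([popt[0], -popt[1], popt[3], popt[2]])
    rss = float(np.sum((_model_logged(conc, *popt) - resp) ** 2))
    ic50 = float(10.0 ** popt[0])
    hill, top, bottom = (float(v) for v in popt[1:])
    converged = bottom < top and hill > 0
    msg = "" if converged else "fitted curve has no decreasing branch"
    if converged:
        ci_low, ci_high = _profile_ci(conc, resp, popt, rss, level=ci_level)
    else:
        ci_low = ci_high = float("nan")
    return FourPLFit(
        ic50=ic50,
        hill=hill,
        top=top,
        bottom=bottom,
        ci_low=ci_low,
        ci_high=ci_high,
        rss=rss,
        converged=converged,
        message=msg,
    )
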