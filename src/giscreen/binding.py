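"""Metal-binding models: ITC single-site isotherm and direct-binding fits.

The forward model for isothermal titration calorimetry follows the
independent (single class of sites) binding model with the standard
perfusion-cell dilution treatment: each injection of volume dV into a cell
of volume V0 displaces a fraction dV/V0 of the cell content, so after i
injections the protein is diluted by the cumulative factor
f_i = prod_j (1 - dV_j/V0) and the cell ligand concentration is
L_i = Ls * (1 - f_i). The bound complex concentration at each step comes
from the ligand-depletion quadratic (exact 1:1 mass action, valid when the
ligand is not in vast excess), and the integrated heat of injection i is

    q_i = V0 * dH * (B_i - B_{i-1} * (1 - dV_i/V0)) + q_dil

with B_0 = 0 and q_dil a constant per-injection dilution-heat offset
(mirroring a blank buffer titration). Units are SI throughout: liters,
molar, joules.

The direct-binding model (for MST-style titrations of a ligand against a
fixed low-concentration target) interpolates an arbitrary signal between
its free and bound plateaus by the bound fraction of the target.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DesignError, GeometryError, GIScreenError, InsufficientDataError

logger = logging.getLogger("giscreen")

__all__ = [
    "ITCGeometry",
    "ITCTitration",
    "BindingFit",
    "DirectBindingSeries",
    "DirectBindingFit",
    "bound_fraction",
    "itc_expected_heats",
    "fit_itc",
    "fit_direct_binding",
]

MIN_INJECTIONS = 8


@dataclass
class ITCGeometry:
    """Cell and syringe geometry of one titration (SI units)."""

    cell_volume: float  # V0, liters
    protein_conc: float  # P0 in the cell at start, molar
    syringe_conc: float  # Ls, molar
    injection_volumes: np.ndarray  # dV_i, liters
    temperature: float = 298.15  # kelvin

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.cell_volume <= 0 or np.any(self.injection_volumes <= 0):
            raise GeometryError("all volumes must be positive")
        if self.protein_conc <= 0 or self.syringe_conc <= 0:
            raise GeometryError("concentrations must be positive")
        if float(self.injection_volumes.sum()) >= self.cell_volume:
            raise GeometryError(
                "total injected volume must stay below the cell volume"
            )


@dataclass
class ITCTitration:
    """Geometry plus the integrated heat of each injection (joules)."""

    geometry: ITCGeometry
    heats: np.ndarray

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if self.heats.shape != self.geometry.injection_volumes.shape:
            raise GIScreenError("one heat per injection required")


@dataclass
class BindingFit:
    Kd: float  # molar
    n_sites: float  # stoichiometry
    dH: float  # J/mol
    q_dil: float  # J per injection
    rss: float
    converged: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class DirectBindingSeries:
    """Signal versus titrated ligand at fixed target concentration."""

    fixed_target_conc: float  # P, molar
    ligand_concs: np.ndarray  # molar
    signals: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        self.ligand_concs = np.asarray(self.ligand_concs, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.fixed_target_conc <= 0:
            raise GIScreenError("target concentration must be positive")
        if np.any(self.ligand_concs < 0):
            raise GIScreenError("ligand concentrations must be non-negative")
        if self.ligand_concs.shape != self.signals.shape:
            raise GIScreenError("one signal per ligand concentration required")


@dataclass
class DirectBindingFit:
    Kd: float
    signal_free: float
    signal_bound: float
    rss: float
    converged: bool
    flags: list[str] = field(default_factory=list)


def bound_fraction(
    P: float | np.ndarray, L: float | np.ndarray, Kd: float, n: float = 1.0
) -> float | np.ndarray:
    """Bound complex concentration from the ligand-depletion quadratic.

    For n independent sites per protein at total protein P and total
    ligand L, mass action gives

        B = ((nP + L + Kd) - sqrt((nP + L + Kd)^2 - 4 nP L)) / 2

    evaluated here in the numerically stable product form. B never exceeds
    min(nP, L) and reduces continuously to the hyperbolic limit
    nP * L/(L + Kd) as P -> 0 and to min(nP, L) as Kd -> 0.
    """
    if Kd <= 0 or n <= 0:
        raise ValueError("Kd and n must be positive")
    P = np.asarray(P, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(P < 0) or np.any(L < 0):
        raise ValueError("P and L must be non-negative")
    s = n * P + L + Kd
    disc = np.sqrt(np.maximum(s * s - 4.0 * n * P * L, 0.0))
    # B = (s - sqrt(s^2-4nPL))/2 rewritten to avoid cancellation
    out = np.where(s + disc > 0, 2.0 * n * P * L / (s + disc), 0.0)
    return float(out) if out.ndim == 0 else out


def itc_expected_heats(geometry: ITCGeometry, params: BindingFit) -> np.ndarray:
    """Forward-model the integrated heat of every injection (joules)."""
    V0 = geometry.cell_volume
    dV = geometry.injection_volumes
    f = np.cumprod(1.0 - dV / V0)
    P = geometry.protein_conc * f
    L = geometry.syringe_conc * (1.0 - f)
    B = bound_fraction(P, L, params.Kd, params.n_sites)
    B_prev = np.concatenate([[0.0], B[:-1]])
    q = V0 * params.dH * (B - B_prev * (1.0 - dV / V0)) + params.q_dil
    return q


def _make_fit(Kd: float, n: float, dH: float, q_dil: float) -> BindingFit:
    return BindingFit(
        Kd=Kd, n_sites=n, dH=dH, q_dil=q_dil, rss=0.0, converged=True
    )


def fit_itc(titration: ITCTitration) -> BindingFit:
    """Fit (Kd, n, dH, q_dil) to integrated injection heats.

    Nonlinear least squares on the independent-site forward model, with Kd
    parameterized on the log10 scale. Initialization: n = 1, dH from the
    heat of the first two injections per mole of ligand delivered, q_dil
    from the tail of the titration, Kd from the molar ratio at the
    steepest heat change. Shallow isotherms (c = n*P0/Kd < 1) converge but
    are flagged ``low_c``; a titration whose fitted binding heat is
    negligible against its scale is flagged ``no_binding``.
    """
    geom = titration.geometry
    q = titration.heats
    if q.size < MIN_INJECTIONS:
        raise InsufficientDataError(
            f"need >= {MIN_INJECTIONS} injections, got {q.size}"
        )
    dV = geom.injection_volumes
    q_dil0 = float(np.mean(q[-2:]))
    delivered = geom.syringe_conc * float(dV[:2].sum())  # moles in first two shots
    dH0 = float((q[:2].sum() - 2.0 * q_dil0) / delivered)
    if dH0 == 0.0:
        dH0 = -1.0
    f = np.cumprod(1.0 - dV / geom.cell_volume)
    molar_ratio = (geom.syringe_conc * (1.0 - f)) / (geom.protein_conc * f)
    steepest = int(np.argmax(np.abs(np.diff(q)))) + 1
    Kd0 = max(
        geom.protein_conc * abs(float(molar_ratio[steepest]) - 1.0),
        geom.protein_conc / 100.0,
    )

    def residuals(x: np.ndarray) -> np.ndarray:
        fit = _make_fit(10.0 ** x[0], x[1], x[2], x[3])
        return itc_expected_heats(geom, fit) - q

    x0 = np.array([math.log10(Kd0), 1.0, dH0, q_dil0])
    scale = np.array([1.0, 1.0, max(abs(dH0), 1e3), max(abs(q_dil0), 1e-8)])
    res = least_squares(
        residuals,
        x0,
        bounds=([-12.0, 0.05, -np.inf, -np.inf], [-2.0, 20.0, np.inf, np.inf]),
        x_scale=scale,
        method="trf",
    )
    Kd, n, dH, q_dil = 10.0 ** res.x[0], res.x[1], res.x[2], res.x[3]
    fit = BindingFit(
        Kd=float(Kd),
        n_sites=float(n),
        dH=float(dH),
        q_dil=float(q_dil),
        rss=float(2.0 * res.cost),
        converged=bool(res.success),
    )
    binding_heat = abs(dH) * n * geom.protein_conc * geom.cell_volume
    heat_scale = float(np.abs(q).sum())
    if binding_heat < max(1e-9, 0.02 * heat_scale):
        fit.flags.append("no_binding")
        logger.warning("titration shows no measurable binding heat")
    c_value = n * geom.protein_conc / Kd
    if c_value < 1.0 and "no_binding" not in fit.flags:
        fit.flags.append("low_c")
        logger.warning("shallow isotherm: c = n*P0/Kd = %.3g < 1", c_value)
    return fit


def fit_direct_binding(series: DirectBindingSeries) -> DirectBindingFit:
    """Fit Kd and the two signal plateaus of a direct-binding titration.

    The signal is modeled as S_free + (S_bound - S_free) * B/P with B from
    the ligand-depletion quadratic at stoichiometry 1. Requires at least
    six distinct positive ligand concentrations spanning >= 1.5 log10
    units; an all-flat signal series is returned flagged degenerate.
    """
    P = series.fixed_target_conc
    L = series.ligand_concs
    S = series.signals
    pos = np.unique(L[L > 0])
    if pos.size < 6 or float(np.log10(pos.max() / pos.min())) < 1.5:
        raise DesignError(
            "need >= 6 distinct positive ligand concentrations spanning "
            ">= 1.5 log10 units"
        )
    if float(np.ptp(S)) < 1e-12:
        return DirectBindingFit(
            Kd=float("nan"),
            signal_free=float(S[0]),
            signal_bound=float(S[0]),
            rss=0.0,
            converged=False,
            flags=["degenerate"],
        )
    s_free0 = float(S[np.argmin(L)])
    s_bound0 = float(S[np.argmax(L)])
    mid = 0.5 * (s_free0 + s_bound0)
    Kd0 = float(pos[np.argmin(np.abs([S[L == d].mean() for d in pos] - np.float64(mid)))])

    def residuals(x: np.ndarray) -> np.ndarray:
        Kd, s_free, s_bound = 10.0 ** x[0], x[1], x[2]
        frac = bound_fraction(P, L, Kd, 1.0) / P
        return s_free + (s_bound - s_free) * frac - S

    x0 = np.array([math.log10(Kd0), s_free0, s_bound0])
    res = least_squares(residuals, x0, bounds=([-12.0, -np.inf, -np.inf], [0.0, np.inf, np.inf]))
    return DirectBindingFit(
        Kd=float(10.0 ** res.x[0]),
        signal_free=float(res.x[1]),
        signal_bound=float(res.x[2]),
        rss=float(2.0 * res.cost),
        converged=bool(res.success),
    )
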