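"""Relative quantum yield, photostability drift and cell-viability scoring.

Quantum yield is measured relative to a reference standard (quinine
sulfate, QY 54% in dilute sulfuric acid) via the gradient method:

    phi_x = phi_st * (Grad_x / Grad_st) * (eta_x^2 / eta_st^2),

where Grad is the slope of integrated fluorescence intensity against
absorbance (kept below ~0.1 to avoid inner-filter effects) and eta the
solvent refractive index.

Viability of treated cell cultures is scored from stained-cell absorbance
as 100 * A_treated / A_control and mapped onto the conventional reactivity
scale (none / mild / moderate / severe).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Absorbance above which inner-filter effects bias the gradient method.
INNER_FILTER_ABSORBANCE = 0.1

#: Reactivity bands on viability percent: lower-inclusive cut-offs.
#: >= 90 none, [70, 90) mild, [30, 70) moderate, < 30 severe.
DEFAULT_REACTIVITY_BANDS: tuple[tuple[float, str], ...] = (
    (90.0, "none"),
    (70.0, "mild"),
    (30.0, "moderate"),
    (0.0, "severe"),
)


@dataclass(frozen=True)
class QyInput:
    grad_x: float
    grad_st: float
    eta_x: float
    eta_st: float
    phi_st: float = 0.54      # quinine sulfate reference

    def __post_init__(self) -> None:
        for name in ("grad_x", "grad_st", "eta_x", "eta_st", "phi_st"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.phi_st > 1:
            raise ValueError("reference quantum yield cannot exceed 1")


def relative_qy(inp: QyInput) -> float:
    """Relative quantum yield phi_x; warns if the result exceeds 1."""
    phi = (inp.phi_st * (inp.grad_x / inp.grad_st)
           * (inp.eta_x**2 / inp.eta_st**2))
    if phi > 1:
        logger.warning("relative quantum yield %.3f exceeds 1; check gradients",
                       phi)
    return float(phi)


def gradient_from_series(absorbances: Sequence[float],
                         integrated_intensities: Sequence[float]) -> float:
    """Slope of integrated fluorescence vs absorbance (intercept free)."""
    a = np.asarray(absorbances, dtype=float)
    f = np.asarray(integrated_intensities, dtype=float)
    if a.size < 3:
        raise ValueError("need at least 3 dilution points")
    if np.unique(a).size < 2:
        raise ValueError("absorbances are constant; the slope is undefined")
    if np.any(a > INNER_FILTER_ABSORBANCE):
        logger.warning(
            "absorbance above %.2f: inner-filter effects may bias the slope",
            INNER_FILTER_ABSORBANCE)
    return float(stats.linregress(a, f).slope)


@dataclass(frozen=True)
class DriftResult:
    retention_pct: float        # 100 * last / first
    slope_pct_per_hour: float   # OLS slope as percent of initial per hour


def photostability_drift(times_s: Sequence[float],
                         intensities: Sequence[float]) -> DriftResult:
    """Summarize an illumination time course as retention and drift slope."""
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("need >= 2 strictly increasing time points")
    if y[0] <= 0:
        raise ValueError("initial intensity must be > 0")
    slope = stats.linregress(t, y).slope
    return DriftResult(
        retention_pct=float(100.0 * y[-1] / y[0]),
        slope_pct_per_hour=float(100.0 * slope / y[0] * 3600.0),
    )


@dataclass(frozen=True)
class ViabilityRecord:
    a_s: float
    a_c: float
    viability_pct: float
    reactivity: str


def classify_reactivity(viability_pct: float,
                        bands: tuple[tuple[float, str], ...]
                        = DEFAULT_REACTIVITY_BANDS) -> str:
    """Map viability percent onto a reactivity class (total, no gaps)."""
    if viability_pct < 0:
        raise ValueError("viability cannot be negative")
    for cutoff, label in bands:
        if viability_pct >= cutoff:
            return label
    return bands[-1][1]


def viability(a_s: float, a_c: float,
              bands: tuple[tuple[float, str], ...] = DEFAULT_REACTIVITY_BANDS
              ) -> ViabilityRecord:
    """Viability percent 100 * A_S / A_C with its reactivity class."""
    if a_c <= 0:
        raise ValueError("control absorbance must be > 0")
    if a_s < 0:
        raise ValueError("treated absorbance cannot be negative")
    pct = 100.0 * a_s / a_c
    return ViabilityRecord(a_s=float(a_s), a_c=float(a_c),
                           viability_pct=float(pct),
                           reactivity=classify_reactivity(pct, bands))


def viability_from_plate(a_s_wells: Sequence[float],
                         a_c_wells: Sequence[float]) -> ViabilityRecord:
    """Plate-level viability: mean of wells per condition, then the ratio.

    Treated and control wells are unpaired on a 96-well plate, so means are
    taken before the ratio.
    """
    a_s = np.asarray(a_s_wells, dtype=float)
    a_c = np.asarray(a_c_wells, dtype=float)
    if a_s.size < 1 or a_c.size < 1:
        raise ValueError("need at least one well per condition")
    return viability(float(np.mean(a_s)), float(np.mean(a_c)))
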