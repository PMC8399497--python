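"""Donor-acceptor association constant from quench titrations.

The donor fluorescence quench as a function of quencher (acceptor)
concentration is linearized with the modified Stern-Volmer (Lehrer)
equation

    F0 / (F0 - F) = 1 / f_a + 1 / (f_a * K * [Q]),

so an ordinary least-squares fit of F0/(F0-F) against 1/[Q] yields the
association constant K = intercept / slope (in M^-1; concentrations are
converted from uM before fitting) and the accessible fraction
f_a = 1 / intercept. For a FRET-quenched donor with Langmuir binding,
f_a equals the asymptotic transfer efficiency at full site occupancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuenchTable:
    """Quencher concentrations (uM) with donor fluorescence F and reference F0."""

    q_conc_uM: np.ndarray
    f0: float
    f: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q_conc_uM, dtype=float)
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "q_conc_uM", q)
        object.__setattr__(self, "f", f)
        if q.ndim != 1 or f.ndim != 1 or q.size != f.size:
            raise ValueError("q_conc_uM and f must be 1-D of equal length")
        if not self.f0 > 0:
            raise ValueError("F0 must be > 0")
        if np.any(q <= 0):
            raise ValueError("quencher concentrations must be > 0")
        if np.any(np.diff(q) <= 0):
            raise ValueError("quencher concentrations must be strictly increasing")
        if np.any(f < 0):
            raise ValueError("fluorescence cannot be negative")
        # small F > F0 excursions are noise; real violations are unit errors
        if np.any(f > 1.02 * self.f0):
            raise ValueError("F exceeds F0 by more than 2%; check units")


@dataclass(frozen=True)
class BindingFit:
    """Result of the modified Stern-Volmer fit."""

    K: float            # association constant, M^-1
    f_a: float          # accessible fraction (asymptotic quench depth)
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("fitted K must be > 0")
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")


def stern_volmer_fit(table: QuenchTable) -> BindingFit:
    """Fit the Lehrer linearization and return (K, f_a, R^2).

    Rows with F == F0 (no quench: F0/(F0-F) undefined) are excluded with a
    warning; at least 3 usable rows are required. The fit is invariant to a
    common rescaling of F0 and F.
    """
    usable = table.f < table.f0
    n_dropped = int(np.sum(~usable))
    if n_dropped:
        logger.warning(
            "excluding %d row(s) with F >= F0 from the Stern-Volmer fit",
            n_dropped)
    q_M = table.q_conc_uM[usable] * 1e-6
    f = table.f[usable]
    if q_M.size < 3:
        raise ValueError(
            f"need at least 3 usable rows with F < F0, got {q_M.size}")
    y = table.f0 / (table.f0 - f)
    x = 1.0 / q_M
    fit = stats.linregress(x, y)
    if fit.slope <= 0 or fit.intercept <= 0:
        raise ValueError(
            "non-positive Stern-Volmer slope or intercept: the quench data "
            "do not follow the Lehrer model")
    k = fit.intercept / fit.slope
    f_a = 1.0 / fit.intercept
    return BindingFit(K=float(k), f_a=float(f_a),
                      r_squared=float(fit.rvalue**2), n_points=int(q_M.size))
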