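"""Förster resonance energy transfer core: overlap integral, Förster
distance, transfer efficiency, spectral unmixing and excitation selection.

Model
-----
A nanoparticle donor transfers excitation energy non-radiatively to ``n``
proximal acceptors at distance ``r``. Efficiency follows the multi-acceptor
point-dipole form

    E = n R0^6 / (n R0^6 + r^6),

with the Förster distance R0 set by the spectral overlap integral

    J = ( ∫ F_D(λ) ε_A(λ) λ^4 dλ ) / ( ∫ F_D(λ) dλ ),

i.e. the donor emission is area-normalized so J is independent of the
arbitrary intensity units of F_D, and

    R0^6 [cm^6] = 8.79e-25 κ² η⁻⁴ φ J [M^-1 cm^3],

where κ² is the orientation factor (2/3 for isotropic averaging), η the
medium refractive index (1.336 for aqueous buffer) and φ the donor quantum
yield. J is reported both in M^-1 cm^-1 nm^4 and in M^-1 cm^3
(1 nm^4 = 1e-28 cm^4), and R0 is cross-checked against the equivalent
Å-scale form R0[Å] = 0.211 (κ² η⁻⁴ φ J[M^-1 cm^-1 nm^4])^(1/6).

Experimentally, efficiency is measured from donor quenching,
E = 1 - F_DA / F_D, with F_DA and F_D the integrated donor emission with
and without acceptor. Donor and acceptor contributions to a composite
spectrum are separated by non-negative least squares against measured
single-species references.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import nnls

from .spectra import (Spectrum, WavelengthWindow, common_grid, integrate,
                      resample)

logger = logging.getLogger(__name__)

#: Förster constant for R0^6 in cm^6 with J in M^-1 cm^3.
FORSTER_CONSTANT_CM = 8.79e-25
#: Equivalent Å-scale prefactor with J in M^-1 cm^-1 nm^4.
FORSTER_CONSTANT_ANGSTROM = 0.211
#: nm^4 -> cm^4 (and hence J conversion between the two conventions).
NM4_TO_CM3 = 1e-28

DEFAULT_KAPPA2 = 2.0 / 3.0
DEFAULT_REFRACTIVE_INDEX = 1.336

#: Donor-band integration window around the 441/456 nm donor emission peak.
DONOR_WINDOW = WavelengthWindow(390.0, 500.0)

#: Relative headroom tolerated on F_DA > F_D before it is a hard error.
EFFICIENCY_NOISE_TOLERANCE = 0.02


@dataclass(frozen=True)
class OverlapIntegral:
    """Spectral overlap in both unit conventions."""

    j_nm4: float    # M^-1 cm^-1 nm^4
    j_cm3: float    # M^-1 cm^3

    def __post_init__(self) -> None:
        if abs(self.j_cm3 - self.j_nm4 * NM4_TO_CM3) > 1e-9 * abs(self.j_cm3):
            raise ValueError("inconsistent overlap-unit pair")


@dataclass(frozen=True)
class FretParams:
    """Photophysical parameter bundle for one donor-acceptor system."""

    j_nm4: float | None = None
    efficiency: float | None = None
    r0_nm: float | None = None
    r_nm: float | None = None
    n_acceptors: float | None = None
    kappa2: float = DEFAULT_KAPPA2
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX
    quantum_yield: float | None = None

    def __post_init__(self) -> None:
        if self.efficiency is not None and not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must lie in [0, 1]")
        if not 0.0 < self.kappa2 <= 4.0:
            raise ValueError("kappa2 must lie in (0, 4]")
        for name in ("r0_nm", "r_nm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0 when set")

    @property
    def j_cm3(self) -> float | None:
        return None if self.j_nm4 is None else self.j_nm4 * NM4_TO_CM3

    def is_consistent(self, rtol: float = 0.05) -> bool | None:
        """Do (E, R0, r, n) jointly satisfy the multi-acceptor relation?

        Returns None when any of the four is missing.
        """
        if None in (self.efficiency, self.r0_nm, self.r_nm, self.n_acceptors):
            return None
        predicted = efficiency_from_distance(self.r_nm, self.r0_nm,
                                             self.n_acceptors)
        return bool(abs(predicted - self.efficiency)
                    <= rtol * max(self.efficiency, 1e-12))


def overlap_integral(donor_emission: Spectrum,
                     acceptor_absorptivity: Spectrum) -> OverlapIntegral:
    """Overlap integral J on the intersected common grid.

    The donor emission is area-normalized internally, so the result is
    invariant to donor intensity rescaling and linear in the acceptor
    molar absorptivity.
    """
    if donor_emission.kind != "emission":
        raise ValueError("donor spectrum must have kind='emission'")
    if acceptor_absorptivity.kind != "molar_absorptivity":
        if acceptor_absorptivity.kind == "absorbance":
            raise ValueError(
                "acceptor given as absorbance; divide by path length and "
                "molar concentration to obtain molar absorptivity first")
        raise ValueError("acceptor spectrum must have kind='molar_absorptivity'")
    grid = common_grid(donor_emission, acceptor_absorptivity)
    fd = resample(donor_emission, grid).values
    eps = resample(acceptor_absorptivity, grid).values
    fd_area = np.trapezoid(fd, grid)
    if fd_area <= 0:
        raise ValueError("donor emission has zero area on the common support")
    j_nm4 = float(np.trapezoid(fd * eps * grid**4, grid) / fd_area)
    return OverlapIntegral(j_nm4=j_nm4, j_cm3=j_nm4 * NM4_TO_CM3)


def forster_distance(j_cm3: float, kappa2: float = DEFAULT_KAPPA2,
                     eta: float = DEFAULT_REFRACTIVE_INDEX,
                     phi: float = 1.0) -> float:
    """Förster distance R0 in nm from J in M^-1 cm^3.

    Internally cross-validated against the Å-scale formulation; the two
    printed constants agree to ~0.4%, so a mismatch beyond 1% indicates a
    unit error in the input.
    """
    for name, v in (("j_cm3", j_cm3), ("kappa2", kappa2), ("eta", eta),
                    ("phi", phi)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    if phi > 1:
        raise ValueError("quantum yield phi cannot exceed 1")
    r0_cm6 = FORSTER_CONSTANT_CM * kappa2 * eta**-4 * phi * j_cm3
    r0_nm = r0_cm6 ** (1.0 / 6.0) * 1e7
    r0_angstrom = FORSTER_CONSTANT_ANGSTROM * (
        kappa2 * eta**-4 * phi * (j_cm3 / NM4_TO_CM3)) ** (1.0 / 6.0)
    if abs(r0_angstrom / 10.0 - r0_nm) > 0.01 * r0_nm:
        logger.warning(
            "Förster-distance unit cross-check failed: %.4g nm (cm-scale) vs "
            "%.4g nm (Å-scale); check J units", r0_nm, r0_angstrom / 10.0)
    return float(r0_nm)


def forster_distance_from_nm4(j_nm4: float, **kwargs) -> float:
    """Convenience wrapper accepting J in M^-1 cm^-1 nm^4."""
    return forster_distance(j_nm4 * NM4_TO_CM3, **kwargs)


def efficiency_from_fluorescence(f_da: float, f_d: float) -> float:
    """E = 1 - F_DA / F_D from integrated donor fluorescence.

    Small violations F_DA > F_D (up to 2%, i.e. noise) clip E to 0 with a
    warning; larger violations raise, since they indicate a unit mistake
    rather than noise.
    """
    if f_d <= 0:
        raise ValueError("donor-only integrated fluorescence must be > 0")
    if f_da < 0:
        raise ValueError("integrated fluorescence cannot be negative")
    if f_da > f_d:
        if f_da <= (1.0 + EFFICIENCY_NOISE_TOLERANCE) * f_d:
            logger.warning(
                "F_DA exceeds F_D by %.2f%% (noise); clipping E to 0",
                100 * (f_da / f_d - 1))
            return 0.0
        raise ValueError(
            f"F_DA = {f_da:g} exceeds F_D = {f_d:g} by more than "
            f"{100 * EFFICIENCY_NOISE_TOLERANCE:.0f}%; check units")
    return float(1.0 - f_da / f_d)


def efficiency_from_distance(r: float, r0: float, n: float = 1.0) -> float:
    """Multi-acceptor efficiency E = n R0^6 / (n R0^6 + r^6)."""
    if r <= 0 or r0 <= 0:
        raise ValueError("r and R0 must be > 0")
    if n <= 0:
        raise ValueError("acceptor count n must be > 0")
    ratio6 = n * (r0 / r) ** 6
    return float(ratio6 / (ratio6 + 1.0))


def distance_from_efficiency(e: float, r0: float, n: float = 1.0) -> float:
    """Invert the efficiency relation: r = R0 (n (1 - E) / E)^(1/6)."""
    if not 0.0 < e < 1.0:
        raise ValueError("efficiency must lie strictly in (0, 1) to invert")
    if r0 <= 0 or n <= 0:
        raise ValueError("R0 and n must be > 0")
    return float(r0 * (n * (1.0 - e) / e) ** (1.0 / 6.0))


@dataclass(frozen=True)
class UnmixResult:
    """Non-negative decomposition of a composite onto two references."""

    donor_coeff: float
    acceptor_coeff: float
    residual_rms: float      # residual RMS as a fraction of composite RMS


def unmix(composite: Spectrum, donor_ref: Spectrum,
          acceptor_ref: Spectrum) -> UnmixResult:
    """Decompose composite ≈ a * donor_ref + b * acceptor_ref, a, b >= 0.

    Deterministic non-negative least squares against measured single-species
    references; near-collinear references (cosine similarity > 0.999) are
    rejected because the split is then unidentifiable.
    """
    grid = common_grid(donor_ref, acceptor_ref)
    lo = max(grid[0], composite.support[0])
    hi = min(grid[-1], composite.support[1])
    if hi <= lo:
        raise ValueError("composite support does not overlap the references")
    grid = grid[(grid >= lo) & (grid <= hi)]
    d = resample(donor_ref, grid).values
    a = resample(acceptor_ref, grid).values
    y = resample(composite, grid).values
    cos = float(np.dot(d, a) / (np.linalg.norm(d) * np.linalg.norm(a)))
    if cos > 0.999:
        raise ValueError(
            f"reference spectra are nearly collinear (cosine {cos:.5f}); "
            "unmixing is unidentifiable")
    design = np.column_stack([d, a])
    coeffs, _ = nnls(design, y)
    resid = y - design @ coeffs
    y_rms = float(np.sqrt(np.mean(y**2)))
    resid_rms = float(np.sqrt(np.mean(resid**2))) / y_rms if y_rms > 0 else 0.0
    return UnmixResult(float(coeffs[0]), float(coeffs[1]), resid_rms)


def select_excitation(candidates: Mapping[float, Spectrum],
                      acceptor_absorptivity: Spectrum) -> float:
    """Excitation wavelength whose donor emission maximizes J.

    Ties are broken toward the lowest excitation wavelength.
    """
    if not candidates:
        raise ValueError("need at least one candidate excitation")
    best_ex, best_j = None, -np.inf
    for ex in sorted(candidates):
        j = overlap_integral(candidates[ex], acceptor_absorptivity).j_nm4
        if j > best_j:
            best_ex, best_j = ex, j
    return float(best_ex)


def check_regime(r: float, r0: float) -> tuple[bool, float]:
    """Is r within the reliable FRET distance window 0.5 R0 < r < 1.5 R0?

    Strict inequalities; returns (verdict, r / R0).
    """
    if r <= 0 or r0 <= 0:
        raise ValueError("r and R0 must be > 0")
    ratio = r / r0
    return (0.5 < ratio < 1.5), float(ratio)


# --------------------------------------------------------------------------
# Titration analysis: unmix -> integrate -> quench extrapolation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationAnalysis:
    """Per-point and asymptotic results of one quench titration.

    ``efficiency`` is the asymptotic (full-occupancy) transfer efficiency
    obtained from the Lehrer extrapolation of the per-point donor quench;
    ``binding`` is the associated modified Stern-Volmer fit.
    """

    concentrations_uM: np.ndarray
    donor_fractions: np.ndarray      # F_DA / F_D per titration point
    apparent_efficiency: np.ndarray  # 1 - F_DA / F_D per point
    efficiency: float
    binding: "binding_mod.BindingFit"  # type: ignore[name-defined]


def analyze_titration(series, donor_window: WavelengthWindow = DONOR_WINDOW
                      ) -> TitrationAnalysis:
    """Recover asymptotic efficiency and binding constant from a titration.

    Each composite is unmixed against the donor-only and acceptor-only
    references; the donor coefficient times the donor-window integral of the
    reference gives F_DA per point (Eq. of donor quenching). Because the
    bound fraction follows theta = K c / (1 + K c), the per-point quench
    1 - F_DA/F_D = theta(c) * E saturates at E only as K c -> inf; the
    modified Stern-Volmer (Lehrer) fit of F0/(F0-F) against 1/[Q] therefore
    yields both K (binding) and E (as the accessible fraction f_a = quench
    depth at saturation).
    """
    from . import binding as binding_mod  # local import avoids a cycle

    f_d = integrate(series.donor_ref, donor_window)
    concs, fractions = [], []
    for c, spec in zip(series.concentrations_uM, series.spectra):
        res = unmix(spec, series.donor_ref, series.acceptor_ref)
        concs.append(float(c))
        fractions.append(res.donor_coeff)
    concs_arr = np.asarray(concs)
    fractions_arr = np.asarray(fractions)
    mask = concs_arr > 0
    table = binding_mod.QuenchTable(
        q_conc_uM=concs_arr[mask],
        f0=f_d,
        f=fractions_arr[mask] * f_d,
    )
    fit = binding_mod.stern_volmer_fit(table)
    return TitrationAnalysis(
        concentrations_uM=concs_arr,
        donor_fractions=fractions_arr,
        apparent_efficiency=1.0 - fractions_arr,
        efficiency=fit.f_a,
        binding=fit,
    )
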