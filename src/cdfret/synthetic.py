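"""Synthetic study data with planted ground truth.

The study's instrument data (carbon-dot emission, riboflavin absorption,
quench titrations, ratiometric calibrations, spiked beverage series and
viability plates) are not deposited anywhere, so this module generates them
from explicit band models and planted parameters. Every generator is a pure
function of its configuration and an integer seed, and returns the planted
truth alongside the data so that downstream estimators can be tested as
recovery problems.

Conditions emulated (fixed once, as the study states them):

* carbon-dot donor emission is excitation dependent, with Gaussian bands
  peaking at 420, 440 and 456 nm for 320, 340 and 360 nm excitation;
* the riboflavin acceptor absorbs around 445 nm (molar absorptivity peak
  1.25e4 M^-1 cm^-1) and emits around 521 nm;
* titrations follow the cuvette protocol: 20 uL steps of a 1000 uM acceptor
  stock into 3 mL of donor solution (10 steps, ~62.5 uM endpoint, dilution
  accounted for);
* donor-acceptor association follows a 1:1 Langmuir isotherm
  theta = K c / (1 + K c) with a single binding constant K;
* the composite emission at bound fraction theta and planted efficiency E is
  (1 - theta E) x donor reference + sensitized acceptor emission
  proportional to theta E, plus optional direct acceptor excitation and
  multiplicative Gaussian noise clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spectra import Spectrum

__all__ = [
    "BandModel",
    "SyntheticConfig",
    "TitrationSeries",
    "CalibrationData",
    "StandardAdditionData",
    "ViabilityPlate",
    "PRESETS",
    "get_preset",
    "default_grid",
    "titration_concentrations",
    "make_donor_emission",
    "make_acceptor_absorptivity",
    "make_acceptor_emission",
    "simulate_titration",
    "simulate_calibration",
    "simulate_standard_addition",
    "simulate_viability_plate",
]


def default_grid(step: float = 1.0) -> np.ndarray:
    """Default instrument grid: 350-650 nm at 1 nm."""
    return np.arange(350.0, 650.0 + step / 2, step)


@dataclass(frozen=True)
class BandModel:
    """Gaussian spectral band: center (nm), sigma (nm), amplitude (value units)."""

    center: float
    sigma: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("band sigma must be > 0")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")
        if not 200.0 <= self.center <= 800.0:
            raise ValueError("band center must lie in 200-800 nm")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        return self.amplitude * np.exp(-((grid - self.center) ** 2)
                                       / (2.0 * self.sigma**2))


#: Excitation-dependent donor bands; amplitudes are per-(mg/mL) specific
#: intensities, largest at 360 nm excitation where the donor is brightest.
DONOR_BANDS: Mapping[float, BandModel] = {
    320.0: BandModel(center=420.0, sigma=25.0, amplitude=600.0),
    340.0: BandModel(center=440.0, sigma=25.0, amplitude=800.0),
    360.0: BandModel(center=456.0, sigma=25.0, amplitude=1000.0),
}

ACCEPTOR_ABSORPTION = BandModel(center=445.0, sigma=20.0, amplitude=1.25e4)
ACCEPTOR_EMISSION = BandModel(center=521.0, sigma=30.0, amplitude=1.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative description of one simulated FRET experiment."""

    donor_bands: Mapping[float, BandModel] = field(
        default_factory=lambda: dict(DONOR_BANDS))
    acceptor_absorption: BandModel = ACCEPTOR_ABSORPTION
    acceptor_emission: BandModel = ACCEPTOR_EMISSION
    binding_K: float = 2.7e4            # M^-1
    planted_E: float = 0.91             # asymptotic FRET efficiency, (0, 1]
    donor_conc: float = 5.0e-3          # mg/mL
    acceptor_concs_uM: tuple[float, ...] = ()  # empty -> titration protocol
    noise_sigma: float = 0.01           # multiplicative, fraction of signal
    seed: int = 0
    excitation: float = 360.0           # nm
    transfer_gain: float = 1.0          # sensitized/quenched amplitude ratio
    acceptor_direct_excitation: float = 0.0  # fraction of donor peak at c_max
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        if not self.binding_K > 0:
            raise ValueError("binding_K must be > 0")
        if not 0.0 < self.planted_E <= 1.0:
            raise ValueError("planted_E must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not self.donor_conc > 0:
            raise ValueError("donor_conc must be > 0")
        concs = np.asarray(self.acceptor_concs_uM, dtype=float)
        if concs.size and (np.any(concs < 0) or np.any(np.diff(concs) <= 0)):
            raise ValueError("acceptor_concs_uM must be nonnegative, increasing")

    @property
    def grid(self) -> np.ndarray:
        return default_grid(self.grid_step)

    def concentrations(self) -> np.ndarray:
        if len(self.acceptor_concs_uM):
            return np.asarray(self.acceptor_concs_uM, dtype=float)
        return titration_concentrations()


def titration_concentrations(n_additions: int = 10, step_uL: float = 20.0,
                             stock_uM: float = 1000.0,
                             start_mL: float = 3.0) -> np.ndarray:
    """Cuvette acceptor concentrations after each titrant addition (uM).

    Successive ``step_uL`` additions of the stock into ``start_mL`` of donor
    solution, dilution included: c_k = stock * k*step / (start + k*step).
    Defaults reproduce the study protocol (endpoint ~62.5 uM after 10 steps).
    """
    k = np.arange(1, n_additions + 1, dtype=float)
    added_mL = k * step_uL / 1000.0
    return stock_uM * added_mL / (start_mL + added_mL)


def make_donor_emission(config: SyntheticConfig, excitation: float,
                        grid: np.ndarray | None = None) -> Spectrum:
    """Donor emission band for a registered excitation wavelength.

    Amplitude scales linearly with ``config.donor_conc``.
    """
    if excitation not in config.donor_bands:
        avail = ", ".join(f"{x:g}" for x in sorted(config.donor_bands))
        raise KeyError(
            f"no donor band registered for excitation {excitation:g} nm "
            f"(available: {avail})")
    grid = config.grid if grid is None else np.asarray(grid, dtype=float)
    band = config.donor_bands[excitation]
    values = band.profile(grid) * config.donor_conc
    return Spectrum(grid, values, kind="emission",
                    meta={"excitation_nm": excitation,
                          "donor_conc_mg_per_mL": config.donor_conc})


def make_acceptor_absorptivity(config: SyntheticConfig | None = None,
                               grid: np.ndarray | None = None) -> Spectrum:
    """Acceptor molar absorptivity spectrum (M^-1 cm^-1)."""
    band = config.acceptor_absorption if config else ACCEPTOR_ABSORPTION
    if grid is None:
        grid = config.grid if config else default_grid()
    return Spectrum(np.asarray(grid, float), band.profile(np.asarray(grid, float)),
                    kind="molar_absorptivity", meta={"species": "acceptor"})


def make_acceptor_emission(config: SyntheticConfig | None = None,
                           grid: np.ndarray | None = None) -> Spectrum:
    """Unit-amplitude acceptor emission reference spectrum."""
    band = config.acceptor_emission if config else ACCEPTOR_EMISSION
    if grid is None:
        grid = config.grid if config else default_grid()
    grid = np.asarray(grid, float)
    prof = band.profile(grid)
    return Spectrum(grid, prof / prof.max(), kind="emission",
                    meta={"species": "acceptor"})


@dataclass(frozen=True)
class TitrationSeries:
    """Ordered (acceptor concentration, composite spectrum) pairs.

    ``spectra[0]`` corresponds to ``concentrations_uM[0] == 0`` and equals
    the donor-only reference up to noise. ``ground_truth`` carries the
    planted (theta vector, efficiency, binding constant) for recovery tests.
    """

    concentrations_uM: np.ndarray
    spectra: tuple[Spectrum, ...]
    donor_ref: Spectrum
    acceptor_ref: Spectrum
    ground_truth: dict

    def __len__(self) -> int:
        return len(self.spectra)


def _apply_noise(values: np.ndarray, sigma: float,
                 rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return values
    noisy = values * (1.0 + rng.normal(0.0, sigma, size=values.shape))
    return np.clip(noisy, 0.0, None)


def simulate_titration(config: SyntheticConfig) -> TitrationSeries:
    """Generate a quench titration with planted efficiency and binding.

    For acceptor concentration c the bound fraction is
    theta = K c / (1 + K c); the composite spectrum is

        (1 - theta E) * donor_ref
        + theta E * transfer_gain * (donor peak) * acceptor_emission_hat
        + direct * (c / c_max) * (donor peak) * acceptor_emission_hat
        + multiplicative noise,

    where acceptor_emission_hat is the unit-peak acceptor band. Sensitized
    amplitude is tied to the donor peak so donor loss and acceptor gain are
    of comparable magnitude, as in the measured titrations.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    donor_ref = make_donor_emission(config, config.excitation, grid)
    acceptor_ref = make_acceptor_emission(config, grid)
    concs = config.concentrations()
    K_per_uM = config.binding_K * 1e-6  # M^-1 -> uM^-1
    theta = K_per_uM * concs / (1.0 + K_per_uM * concs)
    donor_peak = float(donor_ref.values.max())
    c_max = float(concs.max()) if concs.size else 1.0

    spectra = []
    all_concs = np.concatenate(([0.0], concs))
    for c, th in zip(all_concs, np.concatenate(([0.0], theta))):
        composite = (1.0 - th * config.planted_E) * donor_ref.values
        composite = composite + (th * config.planted_E * config.transfer_gain
                                 * donor_peak) * acceptor_ref.values
        if config.acceptor_direct_excitation > 0 and c > 0:
            composite = composite + (config.acceptor_direct_excitation
                                     * (c / c_max) * donor_peak
                                     ) * acceptor_ref.values
        composite = _apply_noise(composite, config.noise_sigma, rng)
        spectra.append(Spectrum(grid, composite, kind="emission",
                                meta={"acceptor_conc_uM": float(c)}))

    truth = {"theta": theta, "planted_E": config.planted_E,
             "binding_K": config.binding_K,
             "apparent_E": theta * config.planted_E}
    return TitrationSeries(all_concs, tuple(spectra), donor_ref, acceptor_ref,
                           truth)


# --------------------------------------------------------------------------
# Ratio-level generators: calibration, standard addition, viability
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationData:
    table: pd.DataFrame          # columns: conc_uM, ratio
    blanks: np.ndarray           # n_blanks ratiometric blank readings
    ground_truth: dict           # slope, intercept, sigma_blank, detection_limit


@dataclass(frozen=True)
class CalibrationPreset:
    """Planted ratiometric calibration: slope and blank noise fix 3*sigma/S."""

    slope: float = 0.12          # ratio per uM
    intercept: float = 0.05     # blank-level ratio
    sigma_blank: float = 1.0e-3  # ratio units; 3*sigma/slope = 0.025 uM
    concs_uM: tuple[float, ...] = tuple(float(c) for c in range(0, 12))

    @property
    def detection_limit(self) -> float:
        return 3.0 * self.sigma_blank / self.slope


def simulate_calibration(preset: CalibrationPreset | None = None,
                         n_blanks: int = 10, seed: int = 0) -> CalibrationData:
    """Ratiometric calibration set plus blank replicates.

    Signals are linear in concentration over the preset range with the
    planted slope; blanks and calibration points share the planted blank
    noise. The planted truth (slope, sigma, detection limit) is returned.
    """
    preset = preset or CalibrationPreset()
    if n_blanks < 2:
        raise ValueError("need at least 2 blank replicates")
    rng = np.random.default_rng(seed)
    concs = np.asarray(preset.concs_uM, dtype=float)
    ratios = (preset.intercept + preset.slope * concs
              + rng.normal(0.0, preset.sigma_blank, size=concs.size))
    blanks = preset.intercept + rng.normal(0.0, preset.sigma_blank, size=n_blanks)
    table = pd.DataFrame({"conc_uM": concs, "ratio": ratios})
    truth = {"slope": preset.slope, "intercept": preset.intercept,
             "sigma_blank": preset.sigma_blank,
             "detection_limit": preset.detection_limit}
    return CalibrationData(table, blanks, truth)


@dataclass(frozen=True)
class StandardAdditionData:
    table: pd.DataFrame          # columns: addition_uM, ratio
    ground_truth: dict           # base_conc_uM, slope, noise_rel


@dataclass(frozen=True)
class StandardAdditionPreset:
    """Spiked-sample series: seven additions, sub-4%-RSD multiplicative noise."""

    slope: float = 0.12                       # ratio per uM, blank-subtracted
    base_conc_uM: float = 2.0
    additions_uM: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0)
    noise_rel: float = 3.0e-3                 # fraction of each ratio


def simulate_standard_addition(preset: StandardAdditionPreset | None = None,
                               base_conc_uM: float | None = None,
                               additions_uM: Sequence[float] | None = None,
                               seed: int = 0) -> StandardAdditionData:
    """Blank-subtracted ratios linear in (base + addition) with planted noise."""
    preset = preset or StandardAdditionPreset()
    base = preset.base_conc_uM if base_conc_uM is None else float(base_conc_uM)
    adds = np.asarray(preset.additions_uM if additions_uM is None
                      else additions_uM, dtype=float)
    if base < 0:
        raise ValueError("base concentration must be >= 0")
    if adds.size < 2 or np.any(np.diff(adds) <= 0):
        raise ValueError("additions must be strictly increasing")
    rng = np.random.default_rng(seed)
    clean = preset.slope * (base + adds)
    ratios = clean * (1.0 + rng.normal(0.0, preset.noise_rel, size=adds.size))
    table = pd.DataFrame({"addition_uM": adds, "ratio": ratios})
    truth = {"base_conc_uM": base, "slope": preset.slope,
             "noise_rel": preset.noise_rel}
    return StandardAdditionData(table, truth)


@dataclass(frozen=True)
class ViabilityPlate:
    a_s: np.ndarray              # treated-well absorbances
    a_c: np.ndarray              # control-well absorbances
    ground_truth: dict


#: Mean viability fractions reported for representative plate conditions:
#: dilute donor at 24 h (~90%, mild), donor-acceptor conjugate at 24 h
#: (~80%, mild), mid concentrations at 48 h (~55%, moderate) and the most
#: concentrated donor at 48 h (~17%, severe).
VIABILITY_CONDITIONS: Mapping[str, float] = {
    "cds_0.01mg_24h": 0.90,
    "cds_rf_conjugate_24h": 0.80,
    "cds_1mg_48h": 0.55,
    "cds_5mg_48h": 0.17,
}


def simulate_viability_plate(treated_mean_fraction: float, n_wells: int = 6,
                             cv: float = 0.08, seed: int = 0,
                             control_absorbance: float = 0.8) -> ViabilityPlate:
    """Control and treated well absorbances with lognormal well variation.

    The lognormal is parameterized so the well *mean* equals the target:
    sigma^2 = ln(1 + cv^2), mu = ln(mean) - sigma^2 / 2. At cv = 0 the wells
    are exact and viability is exactly 100 * treated_mean_fraction.
    """
    if treated_mean_fraction < 0:
        raise ValueError("treated_mean_fraction must be >= 0")
    if n_wells < 1:
        raise ValueError("need at least one well")
    rng = np.random.default_rng(seed)

    def draw(mean: float) -> np.ndarray:
        if mean == 0 or cv == 0:
            return np.full(n_wells, mean)
        s2 = np.log1p(cv**2)
        return rng.lognormal(np.log(mean) - s2 / 2.0, np.sqrt(s2), size=n_wells)

    a_c = draw(control_absorbance)
    a_s = draw(control_absorbance * treated_mean_fraction)
    return ViabilityPlate(a_s, a_c,
                          {"treated_mean_fraction": treated_mean_fraction,
                           "cv": cv})


# --------------------------------------------------------------------------
# Frozen presets: the study conditions by name
# --------------------------------------------------------------------------

PRESETS: dict[str, object] = {
    # low donor concentration -> more acceptors per donor -> higher efficiency
    "low_donor": SyntheticConfig(donor_conc=5.0e-3, planted_E=0.91),
    "high_donor": SyntheticConfig(donor_conc=4.0e-2, planted_E=0.84),
    # quench table for the modified Stern-Volmer fit: fully accessible donor
    "sv_table1": SyntheticConfig(donor_conc=5.0e-3, planted_E=1.0),
    "calibration_dl": CalibrationPreset(),
    "standard_addition": StandardAdditionPreset(),
    "viability": dict(VIABILITY_CONDITIONS),
}


def get_preset(name: str, **overrides):
    """Fetch a frozen preset by name, optionally overriding config fields."""
    try:
        preset = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    if overrides:
        if isinstance(preset, dict):
            raise TypeError(f"preset {name!r} does not accept overrides")
        preset = replace(preset, **overrides)
    return preset
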