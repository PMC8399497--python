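"""Sensor application layer: ratiometric signal, calibration with detection
limit, inverse prediction, standard addition and interference scoring.

The sensor reads out the ratio of acceptor emission (around 521 nm) to
donor emission (around 441 nm). The ratio is linear in analyte
concentration over the working range; the detection limit follows the
3-sigma convention DL = 3 * sd(blanks) / slope. Real samples with matrix
effects are quantified by standard addition: known increments are spiked
into the sample, the response line is extrapolated, and the sample
concentration is the magnitude of the x-intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .spectra import Spectrum, WavelengthWindow, window_mean

#: Default ratiometric windows: 11 nm means centred on 521 and 441 nm.
NUMERATOR_WINDOW = WavelengthWindow(516.0, 526.0)
DENOMINATOR_WINDOW = WavelengthWindow(436.0, 446.0)


@dataclass(frozen=True)
class RatiometricSignal:
    i_num: float    # mean intensity in the acceptor (521 nm) window
    i_den: float    # mean intensity in the donor (441 nm) window

    def __post_init__(self) -> None:
        if self.i_den <= 0:
            raise ValueError("denominator window intensity must be > 0")

    @property
    def ratio(self) -> float:
        return self.i_num / self.i_den


def ratiometric_signal(spectrum: Spectrum,
                       num_window: WavelengthWindow = NUMERATOR_WINDOW,
                       den_window: WavelengthWindow = DENOMINATOR_WINDOW
                       ) -> RatiometricSignal:
    """Window-mean intensities around the acceptor and donor peaks.

    Window means (rather than single-pixel values) make the ratio robust to
    grid alignment; the ratio is invariant under global intensity rescaling.
    """
    return RatiometricSignal(window_mean(spectrum, num_window),
                             window_mean(spectrum, den_window))


@dataclass(frozen=True)
class CalibrationResult:
    slope: float                   # ratio per uM
    intercept: float               # ratio
    r_squared: float
    linear_range: tuple[float, float]   # uM, fitted span
    detection_limit: float         # uM, 3 sigma_blank / |slope|
    n_blanks: int
    sigma_blank: float             # ratio units, sample sd (n-1)


def calibrate(concs_uM: Sequence[float], ratios: Sequence[float],
              blanks: Sequence[float]) -> CalibrationResult:
    """Ordinary least-squares calibration line with 3-sigma detection limit.

    ``sigma_blank`` is the sample standard deviation (n-1 denominator) of
    the blank replicates, the standard analytical convention.
    """
    concs = np.asarray(concs_uM, dtype=float)
    ratios_arr = np.asarray(ratios, dtype=float)
    blanks_arr = np.asarray(blanks, dtype=float)
    if np.unique(concs).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if blanks_arr.size < 2:
        raise ValueError("need at least 2 blank replicates")
    if concs.size != ratios_arr.size:
        raise ValueError("concs and ratios must be the same length")
    fit = stats.linregress(concs, ratios_arr)
    if fit.slope == 0:
        raise ValueError("zero calibration slope: no sensitivity")
    sigma = float(np.std(blanks_arr, ddof=1))
    return CalibrationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        linear_range=(float(concs.min()), float(concs.max())),
        detection_limit=3.0 * sigma / abs(float(fit.slope)),
        n_blanks=int(blanks_arr.size),
        sigma_blank=sigma,
    )


@dataclass(frozen=True)
class Quantification:
    conc_uM: float
    below_detection_limit: bool
    outside_linear_range: bool


def quantify_sample(ratio: float, calibration: CalibrationResult
                    ) -> Quantification:
    """Inverse prediction (ratio - intercept) / slope with quality flags."""
    conc = (ratio - calibration.intercept) / calibration.slope
    return Quantification(
        conc_uM=float(conc),
        below_detection_limit=bool(conc < calibration.detection_limit),
        outside_linear_range=not (calibration.linear_range[0] <= conc
                                  <= calibration.linear_range[1]),
    )


@dataclass(frozen=True)
class StandardAdditionResult:
    estimated_conc_uM: float
    slope: float
    intercept: float
    r_squared: float
    recoveries_pct: np.ndarray   # one per non-zero addition level
    rsd_pct: float


def standard_addition(additions_uM: Sequence[float], ratios: Sequence[float]
                      ) -> StandardAdditionResult:
    """Quantify a sample from spiked increments by x-intercept extrapolation.

    Fits ratio = slope * addition + intercept; the sample concentration is
    |x-intercept| = intercept / slope. Per-level recovery uses the spiked
    increment: found_i = ratio_i / slope (total concentration at level i),
    recovery_i = 100 * (found_i - estimated) / addition_i. The RSD is the
    relative standard deviation of the per-level base estimates
    (found_i - addition_i), a within-series replicate precision.
    """
    adds = np.asarray(additions_uM, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if adds.size < 3 or 0.0 not in adds:
        raise ValueError("need >= 3 additions including a zero addition")
    if np.any(np.diff(adds) <= 0):
        raise ValueError("additions must be strictly increasing")
    if adds.size != r.size:
        raise ValueError("additions and ratios must be the same length")
    fit = stats.linregress(adds, r)
    if fit.slope <= 0:
        raise ValueError("non-positive standard-addition slope: no sensitivity")
    estimated = float(fit.intercept / fit.slope)
    found_total = r / fit.slope
    spiked = adds > 0
    recoveries = 100.0 * (found_total[spiked] - estimated) / adds[spiked]
    base_estimates = found_total - adds
    mean_base = float(np.mean(base_estimates))
    rsd = (100.0 * float(np.std(base_estimates, ddof=1)) / abs(mean_base)
           if mean_base != 0 else float("inf"))
    return StandardAdditionResult(
        estimated_conc_uM=abs(estimated),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        recoveries_pct=recoveries,
        rsd_pct=rsd,
    )


def interference_score(probe_ratio_alone: float,
                       probe_ratio_with_species: float) -> float:
    """Percent change of the probe ratio caused by a coexisting species."""
    if probe_ratio_alone <= 0 or probe_ratio_with_species <= 0:
        raise ValueError("ratios must be positive")
    return float(100.0 * (probe_ratio_with_species - probe_ratio_alone)
                 / probe_ratio_alone)
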