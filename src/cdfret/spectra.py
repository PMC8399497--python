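"""Wavelength-indexed spectra: reading, writing, resampling and integration.

Every downstream computation (overlap integral, donor-quench integration,
ratiometric windows) runs on the :class:`Spectrum` container defined here.
Spectra live on a strictly increasing wavelength grid in nanometres; values
are emission intensity (arbitrary units), absorbance (dimensionless) or
molar absorptivity (M^-1 cm^-1), declared through ``kind`` so that
unit-sensitive operations can refuse mismatched inputs.

Numerical policy: trapezoidal quadrature everywhere (spectra are densely
sampled, trapezoid is robust on irregular grids), linear interpolation for
resampling, and never extrapolation — a grid outside the measured support is
an error, and windows that only partially overlap the support are clipped
with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

logger = logging.getLogger(__name__)

SpectrumKind = Literal["emission", "absorbance", "molar_absorptivity"]

#: Nominal instrument wavelength range (nm) used to validate windows.
INSTRUMENT_RANGE = (200.0, 800.0)


@dataclass(frozen=True)
class WavelengthWindow:
    """Closed wavelength interval [lo, hi] in nm used for band integration."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got [{self.lo}, {self.hi}]")
        if self.lo < INSTRUMENT_RANGE[0] or self.hi > INSTRUMENT_RANGE[1]:
            raise ValueError(
                f"window [{self.lo}, {self.hi}] nm outside instrument range "
                f"{INSTRUMENT_RANGE[0]}-{INSTRUMENT_RANGE[1]} nm"
            )

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass(frozen=True)
class Spectrum:
    """A signal sampled on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths
        Grid in nm, strictly increasing, length >= 2.
    values
        Signal per grid point. Must be finite; molar absorptivity must be
        non-negative.
    kind
        One of ``emission``, ``absorbance``, ``molar_absorptivity``. The
        overlap integral requires an emission donor and a molar-absorptivity
        acceptor, so the kind travels with the data.
    meta
        Free-form provenance (source path, excitation wavelength, ...).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: SpectrumKind = "emission"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D and equally long")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(vals))):
            raise ValueError("wavelengths and values must be finite")
        if self.kind not in ("emission", "absorbance", "molar_absorptivity"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "molar_absorptivity" and np.any(vals < 0):
            raise ValueError("molar absorptivity must be non-negative")

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def with_values(self, values: np.ndarray, **meta) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float),
                       meta={**self.meta, **meta})


def _sniff_delimiter(line: str) -> str:
    # comma or tab auto-detection; whitespace-separated falls back to None-split
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return " "


def read_spectrum(path: str | Path, kind: SpectrumKind = "emission") -> Spectrum:
    """Read a 2-column delimited text spectrum (wavelength_nm, value).

    Comma or tab delimited, auto-detected; ``#``-prefixed lines and a single
    leading non-numeric header row are skipped. Rows are sorted ascending by
    wavelength and duplicate wavelengths are collapsed by arithmetic mean.
    A non-numeric row beyond the header raises with the offending line number.
    """
    path = Path(path)
    wl: list[float] = []
    vals: list[float] = []
    header_allowed = True
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            delim = _sniff_delimiter(line)
            parts = [p for p in (line.split(delim) if delim != " " else line.split())
                     if p.strip() != ""]
            try:
                x, y = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                if header_allowed:
                    header_allowed = False
                    continue
                raise ValueError(
                    f"{path}: non-numeric data on line {lineno}: {line!r}"
                ) from None
            header_allowed = False
            wl.append(x)
            vals.append(y)
    if len(wl) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    wl_arr = np.asarray(wl)
    val_arr = np.asarray(vals)
    order = np.argsort(wl_arr, kind="stable")
    wl_arr, val_arr = wl_arr[order], val_arr[order]
    uniq, inverse, counts = np.unique(wl_arr, return_inverse=True, return_counts=True)
    if uniq.size != wl_arr.size:
        summed = np.zeros_like(uniq)
        np.add.at(summed, inverse, val_arr)
        wl_arr, val_arr = uniq, summed / counts
    return Spectrum(wl_arr, val_arr, kind=kind, meta={"source": str(path)})


def write_spectrum(spectrum: Spectrum, path: str | Path, delimiter: str = ",") -> Path:
    """Write wavelength/value pairs at 17 significant digits (round-trip exact)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kind: {spectrum.kind}\nwavelength_nm{delimiter}value\n")
        for x, y in zip(spectrum.wavelengths, spectrum.values):
            fh.write(f"{x:.17g}{delimiter}{y:.17g}\n")
    return path


def resample(spectrum: Spectrum, grid: Iterable[float]) -> Spectrum:
    """Linearly interpolate onto ``grid`` (strictly increasing, inside support)."""
    grid = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid,
                      dtype=float)
    if grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")
    lo, hi = spectrum.support
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] outside spectrum support [{lo}, {hi}]; "
            "refusing to extrapolate"
        )
    vals = np.interp(grid, spectrum.wavelengths, spectrum.values)
    return Spectrum(grid, vals, kind=spectrum.kind,
                    meta={**spectrum.meta, "resampled": True})


def _clip_window(spectrum: Spectrum, window: WavelengthWindow) -> tuple[float, float]:
    lo, hi = spectrum.support
    if window.hi <= lo or window.lo >= hi:
        raise ValueError(
            f"window [{window.lo}, {window.hi}] nm does not overlap spectrum "
            f"support [{lo}, {hi}] nm"
        )
    clipped = (max(window.lo, lo), min(window.hi, hi))
    if clipped != (window.lo, window.hi):
        logger.warning(
            "window [%s, %s] clipped to spectrum support [%s, %s]",
            window.lo, window.hi, *clipped,
        )
    return clipped


def integrate(spectrum: Spectrum, window: WavelengthWindow | None = None) -> float:
    """Trapezoidal integral of the spectrum, optionally over a window.

    Window endpoints inside the support are included by linear interpolation;
    a window partially outside the support is clipped (with a warning), and a
    window with no overlap is an error. Units: value-units x nm.
    """
    wl, vals = spectrum.wavelengths, spectrum.values
    if window is None:
        return float(np.trapezoid(vals, wl))
    lo, hi = _clip_window(spectrum, window)
    inner = (wl > lo) & (wl < hi)
    xs = np.concatenate(([lo], wl[inner], [hi]))
    ys = np.concatenate((
        [np.interp(lo, wl, vals)], vals[inner], [np.interp(hi, wl, vals)]
    ))
    return float(np.trapezoid(ys, xs))


def window_mean(spectrum: Spectrum, window: WavelengthWindow) -> float:
    """Mean signal over a window: integral divided by the (clipped) width."""
    lo, hi = _clip_window(spectrum, window)
    return integrate(spectrum, WavelengthWindow(lo, hi)) / (hi - lo)


def normalize(spectrum: Spectrum, mode: Literal["peak", "area"] = "peak") -> Spectrum:
    """Rescale to unit peak (``peak``) or unit trapezoidal area (``area``)."""
    if mode == "peak":
        denom = float(np.max(np.abs(spectrum.values)))
    elif mode == "area":
        denom = integrate(spectrum)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if denom == 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return spectrum.with_values(spectrum.values / denom, normalized=mode)


def common_grid(a: Spectrum, b: Spectrum) -> np.ndarray:
    """Shared grid on the intersection of two supports, at the finer step."""
    lo = max(a.support[0], b.support[0])
    hi = min(a.support[1], b.support[1])
    if hi <= lo:
        raise ValueError(
            f"spectra supports {a.support} and {b.support} are disjoint"
        )
    step = min(float(np.median(np.diff(a.wavelengths))),
               float(np.median(np.diff(b.wavelengths))))
    n = max(int(round((hi - lo) / step)) + 1, 2)
    return np.linspace(lo, hi, n)
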