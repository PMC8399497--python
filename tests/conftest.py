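import numpy as np
import pytest

from cdfret.spectra import Spectrum


def gaussian_spectrum(center: float, sigma: float, amplitude: float = 1.0,
                      lo: float = 350.0, hi: float = 650.0, step: float = 1.0,
                      kind: str = "emission") -> Spectrum:
    grid = np.arange(lo, hi + step / 2, step)
    values = amplitude * np.exp(-((grid - center) ** 2) / (2 * sigma**2))
    return Spectrum(grid, values, kind=kind)


@pytest.fixture
def donor_band() -> Spectrum:
    """Donor-like emission band: 456 nm, sigma 25 nm."""
    return gaussian_spectrum(456.0, 25.0, amplitude=100.0)


@pytest.fixture
def acceptor_band() -> Spectrum:
    """Acceptor-like molar absorptivity band: 445 nm, sigma 20 nm."""
    return gaussian_spectrum(445.0, 20.0, amplitude=1.2e4,
                             kind="molar_absorptivity")
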