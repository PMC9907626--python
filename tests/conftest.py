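import numpy as np
import pytest

from hsicolor import (
    ColorimetryContext,
    ReflectanceSpectrum,
    SkinSpectrumParams,
    SpectralAxis,
    make_skin_spectrum,
)


@pytest.fixture(scope="session")
def ctx() -> ColorimetryContext:
    """Default colorimetry context: D65, 10-degree observer, 420-730 nm."""
    return ColorimetryContext()


@pytest.fixture(scope="session")
def full_ctx() -> ColorimetryContext:
    """Full-range context for spectroradiometer-style spectra."""
    return ColorimetryContext(integration_range_nm=(380.0, 780.0))


@pytest.fixture(scope="session")
def axis() -> SpectralAxis:
    return SpectralAxis.standard()


@pytest.fixture(scope="session")
def skin_spectrum(axis) -> ReflectanceSpectrum:
    return make_skin_spectrum(SkinSpectrumParams(), axis)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_smooth_spectrum(rng, wavelengths):
    """Random smooth positive spectrum in (0.05, 0.95) on given wavelengths."""
    n_modes = 4
    wl = np.asarray(wavelengths, dtype=float)
    x = (wl - wl[0]) / (wl[-1] - wl[0])
    values = 0.5 + sum(
        rng.uniform(-0.1, 0.1) * np.sin((k + 1) * np.pi * x + rng.uniform(0, np.pi))
        for k in range(n_modes)
    )
    return ReflectanceSpectrum(wl, np.clip(values, 0.05, 0.95))
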