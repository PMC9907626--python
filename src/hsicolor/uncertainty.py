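"""Propagation of spectral measurement noise to CIELAB uncertainties.

The imager's per-band spectral uncertainty is about 2% (fractional), and
bands and pixels are treated as statistically independent — the assumption
under which ROI averaging reduces the per-pixel sigma by sqrt(n_pixels)
and before/after differences add in quadrature. First-order propagation
uses a finite-difference Jacobian of the spectrum→Lab map; a Monte-Carlo
routine provides the independent check.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorimetry import ColorimetryContext, _lab_f, spectrum_to_xyz
from .errors import ValidationError
from .spectral import ReflectanceSpectrum

#: Central-difference step in reflectance units; robust across the CIELAB
#: f(t) kink at low signal.
_FD_STEP = 1e-4


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative per-band noise: sigma_band = fractional_sigma * R_band."""

    fractional_sigma: float = 0.02

    def __post_init__(self) -> None:
        if self.fractional_sigma < 0:
            raise ValidationError("fractional sigma must be >= 0")

    def band_sigma(self, reflectance: np.ndarray) -> np.ndarray:
        return self.fractional_sigma * np.asarray(reflectance, dtype=float)


@dataclass(frozen=True)
class LabUncertainty:
    """1-sigma uncertainties on L*, a*, b*."""

    sigma_L: float
    sigma_a: float
    sigma_b: float

    def __post_init__(self) -> None:
        if min(self.sigma_L, self.sigma_a, self.sigma_b) < 0:
            raise ValidationError("sigmas must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma_L, self.sigma_a, self.sigma_b])


def _lab_of_reflectance(refl_grid: np.ndarray, ctx: ColorimetryContext) -> np.ndarray:
    """Lab of reflectance sampled on the context grid; vectorised over columns."""
    xyz = ctx.weights.T @ refl_grid
    f = _lab_f(xyz / np.asarray(ctx.white_point)[:, None])
    return np.stack([116.0 * f[1] - 16.0, 500.0 * (f[0] - f[1]), 200.0 * (f[1] - f[2])])


def propagate_to_lab(
    spectrum: ReflectanceSpectrum,
    noise: NoiseModel,
    ctx: ColorimetryContext,
) -> LabUncertainty:
    """First-order (Jacobian) propagation of band noise to Lab sigmas.

    The Jacobian of the band-reflectance→Lab map is taken by central finite
    differences (step 1e-4 in reflectance); with independent bands,
    ``sigma_k^2 = sum_b (J[k, b] * sigma_b)^2``. A zero spectrum is handled
    by the linear branch of the CIELAB f(t) function.
    """
    mat = ctx.resample_matrix(spectrum.wavelengths_nm)
    n_bands = spectrum.reflectance.size
    base = spectrum.reflectance.astype(float)
    # perturbed spectra as columns: [+h per band | -h per band]
    plus = np.repeat(base[:, None], n_bands, axis=1) + _FD_STEP * np.eye(n_bands)
    minus = np.repeat(base[:, None], n_bands, axis=1) - _FD_STEP * np.eye(n_bands)
    lab_all = _lab_of_reflectance(mat @ np.hstack([plus, minus]), ctx)
    jac = (lab_all[:, :n_bands] - lab_all[:, n_bands:]) / (2.0 * _FD_STEP)
    sigma = np.sqrt(((jac * noise.band_sigma(base)[None, :]) ** 2).sum(axis=1))
    return LabUncertainty(float(sigma[0]), float(sigma[1]), float(sigma[2]))


def monte_carlo_lab_sigma(
    spectrum: ReflectanceSpectrum,
    noise: NoiseModel,
    ctx: ColorimetryContext,
    n_draws: int = 10_000,
    rng: np.random.Generator | None = None,
) -> LabUncertainty:
    """Monte-Carlo estimate of the Lab sigmas (oracle for propagate_to_lab).

    Draws multiplicative Gaussian band noise, maps each draw through the
    exact spectrum→Lab chain, and reports the sample SD per channel.
    Negative draws clip to zero (physical reflectance).
    """
    if n_draws < 2:
        raise ValidationError("need at least 2 draws")
    rng = np.random.default_rng() if rng is None else rng
    mat = ctx.resample_matrix(spectrum.wavelengths_nm)
    base = spectrum.reflectance.astype(float)
    draws = base[:, None] * (
        1.0 + noise.fractional_sigma * rng.standard_normal((base.size, n_draws))
    )
    np.clip(draws, 0.0, None, out=draws)
    lab = _lab_of_reflectance(mat @ draws, ctx)
    sd = lab.std(axis=1, ddof=1)
    return LabUncertainty(float(sd[0]), float(sd[1]), float(sd[2]))


def roi_mean_sigma(sigma_pixel: float, n_pixels: int) -> float:
    """Uncertainty of an ROI-mean value: per-pixel sigma / sqrt(n_pixels)."""
    if n_pixels < 1:
        raise ValidationError("n_pixels must be >= 1")
    if sigma_pixel < 0:
        raise ValidationError("sigma must be >= 0")
    return sigma_pixel / np.sqrt(n_pixels)


def difference_sigma(sigma1: float, sigma2: float) -> float:
    """Uncertainty of a difference of two uncorrelated values (quadrature)."""
    if sigma1 < 0 or sigma2 < 0:
        raise ValidationError("sigmas must be >= 0")
    return float(np.hypot(sigma1, sigma2))
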