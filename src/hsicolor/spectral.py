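"""Datacube data model and the calibration chain from raw CCD counts to
fractional reflectance.

The imager records one monochrome frame per tuned bandpass; a *datacube*
stacks those frames into a ``[band, row, col]`` voxel grid. Calibration
follows the standard CCD chain: dark-count subtraction, flat-field
correction for pixel-to-pixel response non-uniformity, and normalisation
against the system's response to a white standard of known reflectance
(0.99), giving the fraction of incident light reflected per voxel.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import CalibrationError, ValidationError

logger = logging.getLogger(__name__)

#: Reflectance values above this ceiling are clipped. The ceiling sits above
#: 1.0 so that specular/noise excursions beyond the 99% white standard survive
#: into the uncertainty analysis instead of being silently flattened.
REFLECTANCE_CEILING = 1.2

_ALLOWED_FWHM = (10.0, 18.0, 32.0)


@dataclass(frozen=True)
class SpectralAxis:
    """Band centers (nm) of a spectral-scanning sequence.

    The standard acquisition sequence is 31 bands spanning 420-730 nm at the
    32 nm FWHM bandwidth setting.
    """

    wavelengths_nm: np.ndarray
    bandwidth_fwhm_nm: float = 32.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        if wl.ndim != 1 or wl.size < 1:
            raise ValidationError("spectral axis needs at least one band")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("band centers must be strictly increasing")
        if wl[0] < 420.0 - 1e-9 or wl[-1] > 730.0 + 1e-9:
            raise ValidationError(
                f"band centers must lie within [420, 730] nm, got "
                f"[{wl[0]:g}, {wl[-1]:g}]"
            )
        if self.bandwidth_fwhm_nm not in _ALLOWED_FWHM:
            raise ValidationError(
                f"bandwidth FWHM must be one of {_ALLOWED_FWHM} nm"
            )

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    @classmethod
    def standard(cls) -> "SpectralAxis":
        """The default 31-band sequence: 420-730 nm, 32 nm FWHM."""
        return cls(np.linspace(420.0, 730.0, 31), 32.0)


@dataclass(frozen=True)
class RawFrame:
    """One uncalibrated frame: CCD counts in a single tuned bandpass."""

    counts: np.ndarray
    wavelength_nm: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2:
            raise ValidationError("frame counts must be a 2-D grid")
        if np.any(counts < 0):
            raise ValidationError("CCD counts cannot be negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape  # type: ignore[return-value]


@dataclass
class CalibrationSet:
    """Dark frame, flat field, and white-standard cube for one acquisition.

    The flat field is normalised to mean 1 on ingest so applying it is
    gain-neutral; it may be a single 2-D grid shared by all bands or a
    per-band 3-D stack.
    """

    dark: np.ndarray
    flat: np.ndarray
    white_cube: np.ndarray
    white_reflectance: float = 0.99

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.flat = np.asarray(self.flat, dtype=float)
        self.white_cube = np.asarray(self.white_cube, dtype=float)
        if self.dark.ndim != 2:
            raise ValidationError("dark frame must be 2-D")
        if self.white_cube.ndim != 3:
            raise ValidationError("white cube must be 3-D [band, row, col]")
        if self.white_cube.shape[1:] != self.dark.shape:
            raise ValidationError("white cube and dark frame shapes differ")
        if self.flat.ndim not in (2, 3):
            raise ValidationError("flat field must be 2-D or per-band 3-D")
        if self.flat.shape[-2:] != self.dark.shape:
            raise ValidationError("flat field and dark frame shapes differ")
        if np.any(self.flat <= 0):
            raise ValidationError("flat field must be strictly positive")
        if not 0 < self.white_reflectance <= 1:
            raise ValidationError("white standard reflectance must be in (0, 1]")
        # normalise each flat plane to mean 1 (gain-neutral)
        if self.flat.ndim == 2:
            self.flat = self.flat / self.flat.mean()
        else:
            self.flat = self.flat / self.flat.mean(axis=(1, 2), keepdims=True)

    def flat_for_band(self, band: int) -> np.ndarray:
        return self.flat if self.flat.ndim == 2 else self.flat[band]


@dataclass
class ReflectanceCube:
    """Calibrated datacube: fractional reflectance per ``[band, row, col]``."""

    values: np.ndarray
    axis: SpectralAxis
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("cube values must be 3-D [band, row, col]")
        if self.values.shape[0] != len(self.axis):
            raise ValidationError(
                f"cube has {self.values.shape[0]} bands but the axis lists "
                f"{len(self.axis)}"
            )
        if np.any(self.values < 0) or np.any(self.values > REFLECTANCE_CEILING):
            raise ValidationError(
                f"reflectance must lie in [0, {REFLECTANCE_CEILING}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.values.shape[1:]  # type: ignore[return-value]


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """A single reflectance spectrum, e.g. the mean over an ROI."""

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        refl = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "reflectance", refl)
        if wl.shape != refl.shape or wl.ndim != 1:
            raise ValidationError("wavelengths and reflectance must be equal-length 1-D")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if np.any(refl < 0) or np.any(refl > REFLECTANCE_CEILING):
            raise ValidationError(
                f"reflectance must lie in [0, {REFLECTANCE_CEILING}]"
            )
        if self.sigma is not None:
            sig = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", sig)
            if sig.shape != wl.shape or np.any(sig < 0):
                raise ValidationError("sigma must match wavelengths and be >= 0")


def dark_correct(counts: np.ndarray, dark: np.ndarray) -> np.ndarray:
    """Subtract the dark frame, clamping negative residuals to zero.

    Counts are physical, so a pixel darker than its dark reference is noise;
    such pixels are clamped and a warning is logged.
    """
    counts = np.asarray(counts, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if counts.shape != dark.shape:
        raise ValidationError(
            f"frame shape {counts.shape} != dark shape {dark.shape}"
        )
    out = counts - dark
    n_neg = int(np.count_nonzero(out < 0))
    if n_neg:
        logger.warning("dark_correct: clamped %d negative pixels to 0", n_neg)
        out = np.maximum(out, 0.0)
    return out


def flat_correct(frame: np.ndarray, flat: np.ndarray) -> np.ndarray:
    """Divide a frame by the flat-field gain map."""
    frame = np.asarray(frame, dtype=float)
    flat = np.asarray(flat, dtype=float)
    if frame.shape != flat.shape:
        raise ValidationError(
            f"frame shape {frame.shape} != flat shape {flat.shape}"
        )
    if np.any(flat <= 0):
        raise ValidationError("flat field must be strictly positive")
    return frame / flat


def compute_reflectance(
    raw_cube: Sequence[RawFrame],
    calib: CalibrationSet,
    axis: SpectralAxis | None = None,
    ceiling: float = REFLECTANCE_CEILING,
) -> ReflectanceCube:
    """Convert a sequence of raw band frames into a reflectance cube.

    Per voxel, ``R = rho_white * (S - D) / (W - D)`` with flat correction
    applied to both the dark-corrected sample ``S`` and white ``W`` frames,
    where ``rho_white`` is the known reflectance of the white standard.
    Frames may arrive in any acquisition order; bands are stored ascending in
    wavelength and the acquisition order is kept in provenance.
    """
    if len(raw_cube) != calib.white_cube.shape[0]:
        raise ValidationError(
            f"{len(raw_cube)} raw frames but white cube has "
            f"{calib.white_cube.shape[0]} bands"
        )
    wavelengths = np.array([f.wavelength_nm for f in raw_cube], dtype=float)
    order = np.argsort(wavelengths)
    if axis is None:
        axis = SpectralAxis(wavelengths[order])
    elif not np.allclose(np.sort(wavelengths), axis.wavelengths_nm):
        raise ValidationError("raw frame wavelengths do not match the axis")

    n_clipped = 0
    planes = []
    for out_band, src in enumerate(order):
        frame = raw_cube[src]
        if frame.shape != calib.dark.shape:
            raise ValidationError(
                f"frame {src} shape {frame.shape} != calibration shape "
                f"{calib.dark.shape}"
            )
        flat = calib.flat_for_band(out_band)
        w_corr = flat_correct(calib.white_cube[src] - calib.dark, flat)
        bad = w_corr <= 0
        if np.any(bad):
            r, c = np.argwhere(bad)[0]
            raise CalibrationError(
                f"white minus dark non-positive at band {src} "
                f"({frame.wavelength_nm:g} nm), pixel ({r}, {c})"
            )
        s_corr = flat_correct(dark_correct(frame.counts, calib.dark), flat)
        refl = calib.white_reflectance * s_corr / w_corr
        n_clipped += int(np.count_nonzero(refl > ceiling))
        planes.append(np.clip(refl, 0.0, ceiling))

    if n_clipped:
        logger.warning(
            "compute_reflectance: clipped %d voxels above ceiling %.3g",
            n_clipped, ceiling,
        )
    provenance = {
        "white_reflectance": calib.white_reflectance,
        "acquisition_order": [int(i) for i in np.argsort(order)],
        "n_clipped_above_ceiling": n_clipped,
    }
    return ReflectanceCube(np.stack(planes), axis, provenance)


def voxel_count(
    cube: ReflectanceCube | tuple[int, int, int]
) -> tuple[int, int]:
    """Total voxel count and its megavoxel rounding.

    Accepts a cube or a bare ``(bands, rows, cols)`` shape, so full-frame
    bookkeeping does not require allocating the cube: the standard sequence
    (31 bands x 2016 x 2016 pixels) holds 125,991,936 voxels, i.e. 126
    megavoxels.
    """
    shape = cube.shape if isinstance(cube, ReflectanceCube) else tuple(cube)
    if len(shape) != 3 or any(int(s) < 1 for s in shape):
        raise ValidationError("shape must be three positive extents")
    n = int(np.prod([int(s) for s in shape]))
    return n, round(n / 1_000_000)


def mean_spectrum(
    cube: ReflectanceCube,
    mask: np.ndarray,
    with_sigma: bool = False,
) -> ReflectanceSpectrum:
    """Mean reflectance spectrum over a pixel mask.

    ``mask`` is a boolean image-shaped array. With ``with_sigma`` the
    standard error of the mean (sample SD / sqrt(n)) is attached per band.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.image_shape:
        raise ValidationError(
            f"mask shape {mask.shape} != image shape {cube.image_shape}"
        )
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValidationError("mask selects no pixels")
    pix = cube.values[:, mask]  # (bands, n)
    mean = pix.mean(axis=1)
    sigma = None
    if with_sigma:
        sd = pix.std(axis=1, ddof=1) if n > 1 else np.zeros_like(mean)
        sigma = sd / np.sqrt(n)
    return ReflectanceSpectrum(cube.axis.wavelengths_nm.copy(), mean, sigma)
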