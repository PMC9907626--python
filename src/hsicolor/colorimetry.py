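"""CIE colorimetry: reflectance spectra and cubes to XYZ, CIELAB, delta E,
and sRGB renderings.

All color math uses the CIE 1964 10-degree standard observer under D65
illumination, the configuration used for skin-color evaluation with both
the hyperspectral imager and the reference spectroradiometer. The observer
and illuminant tables ship with the package on a 5 nm grid.

Tristimulus values follow the standard quadrature

    X = k * sum( R(l) * S(l) * xbar(l) * dl ),   k = 100 / sum( S * ybar * dl )

with the normalisation ``k`` computed over the same integration range as the
sums, so a perfect diffuser (R = 1) maps to Y = 100 and Lab (100, 0, 0)
exactly by construction. The default range is the imager's own spectral
support, 420-730 nm; a 380-780 nm mode suits full-range spectroradiometer
spectra.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import ValidationError
from .spectral import ReflectanceCube, ReflectanceSpectrum

_DELTA = 6.0 / 29.0  # CIELAB f(t) kink at t = _DELTA**3


def _load_table(name: str) -> np.ndarray:
    with resources.files("hsicolor.data").joinpath(name).open("r") as fh:
        return np.loadtxt(fh, delimiter=",", skiprows=1)


@dataclass(frozen=True)
class LabColor:
    L_star: float
    a_star: float
    b_star: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L_star, self.a_star, self.b_star], dtype=float)


@dataclass
class LabImage:
    """Per-pixel L*, a*, b* planes for one calibrated image."""

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray
    context_id: str = ""

    def __post_init__(self) -> None:
        if not (self.L.shape == self.a.shape == self.b.shape):
            raise ValidationError("L, a, b planes must share one shape")
        for plane in (self.L, self.a, self.b):
            if not np.all(np.isfinite(plane)):
                raise ValidationError("Lab planes must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape  # type: ignore[return-value]


class ColorimetryContext:
    """Observer/illuminant tables and integration range for all conversions.

    Parameters
    ----------
    integration_range_nm:
        Wavelength window for the tristimulus quadrature. The default
        (420, 730) matches the imager's spectral support; use (380, 780)
        for full-range spectroradiometer spectra (out-of-support reflectance
        is then required from the input spectrum).
    """

    GRID_STEP_NM = 5.0

    def __init__(self, integration_range_nm: tuple[float, float] = (420.0, 730.0)):
        cmf_tab = _load_table("cie1964_10deg_5nm.csv")
        spd_tab = _load_table("d65_5nm.csv")
        if not np.array_equal(cmf_tab[:, 0], spd_tab[:, 0]):
            raise ValidationError("observer and illuminant grids differ")
        lo, hi = float(integration_range_nm[0]), float(integration_range_nm[1])
        support = (cmf_tab[0, 0], cmf_tab[-1, 0])
        if lo >= hi or lo < support[0] or hi > support[1]:
            raise ValidationError(
                f"integration range must lie within tabulated support {support}"
            )
        sel = (cmf_tab[:, 0] >= lo - 1e-9) & (cmf_tab[:, 0] <= hi + 1e-9)
        self.integration_range_nm = (lo, hi)
        self.grid_nm: np.ndarray = cmf_tab[sel, 0]
        self.cmf: np.ndarray = cmf_tab[sel, 1:4]  # columns xbar, ybar, zbar
        self.illuminant: np.ndarray = spd_tab[sel, 1]
        # k normalises Y of the perfect diffuser to exactly 100 on this range
        self.k: float = 100.0 / float(self.illuminant @ self.cmf[:, 1])
        # weights such that XYZ = weights.T @ R_on_grid
        self.weights: np.ndarray = self.k * self.illuminant[:, None] * self.cmf
        wp = self.weights.sum(axis=0)
        self.white_point: tuple[float, float, float] = (wp[0], wp[1], wp[2])

    @property
    def context_id(self) -> str:
        lo, hi = self.integration_range_nm
        return f"CIE1964-10deg/D65/{lo:g}-{hi:g}nm"

    def resample_matrix(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Linear-interpolation matrix from band samples onto the 5 nm grid.

        Band values are treated as point samples at band centers; the grid
        endpoints clamp to the nearest band (matching ``np.interp``). The
        spectrum must cover the integration range to within half the grid
        step — narrower support raises, with a hint to truncate the range.
        """
        wl = np.asarray(wavelengths_nm, dtype=float)
        tol = self.GRID_STEP_NM / 2.0 + 1e-9
        lo, hi = self.integration_range_nm
        if wl[0] > lo + tol or wl[-1] < hi - tol:
            raise ValidationError(
                f"spectrum support [{wl[0]:g}, {wl[-1]:g}] nm does not cover "
                f"the integration range [{lo:g}, {hi:g}] nm; truncate the "
                f"context range or supply a wider spectrum"
            )
        idx = np.clip(np.searchsorted(wl, self.grid_nm), 1, wl.size - 1)
        left, right = wl[idx - 1], wl[idx]
        frac = np.clip((self.grid_nm - left) / (right - left), 0.0, 1.0)
        mat = np.zeros((self.grid_nm.size, wl.size))
        rows = np.arange(self.grid_nm.size)
        mat[rows, idx - 1] = 1.0 - frac
        mat[rows, idx] = frac
        return mat


def spectrum_to_xyz(
    spectrum: ReflectanceSpectrum, ctx: ColorimetryContext
) -> np.ndarray:
    """Tristimulus XYZ of a reflectance spectrum under the context's tables."""
    mat = ctx.resample_matrix(spectrum.wavelengths_nm)
    return ctx.weights.T @ (mat @ spectrum.reflectance)


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    cube = np.cbrt(np.maximum(t, 0.0))
    lin = t / (3.0 * _DELTA**2) + 4.0 / 29.0
    return np.where(t > _DELTA**3, cube, lin)


def _lab_f_inv(ft: np.ndarray) -> np.ndarray:
    ft = np.asarray(ft, dtype=float)
    return np.where(ft > _DELTA, ft**3, 3.0 * _DELTA**2 * (ft - 4.0 / 29.0))


def xyz_to_lab(xyz: np.ndarray, ctx: ColorimetryContext) -> LabColor:
    """Standard CIELAB transform relative to the context white point."""
    xyz = np.asarray(xyz, dtype=float)
    if np.any(xyz < 0):
        raise ValidationError("tristimulus values must be non-negative")
    fx, fy, fz = _lab_f(xyz / np.asarray(ctx.white_point))
    return LabColor(
        float(116.0 * fy - 16.0),
        float(500.0 * (fx - fy)),
        float(200.0 * (fy - fz)),
    )


def spectrum_to_lab(
    spectrum: ReflectanceSpectrum, ctx: ColorimetryContext
) -> LabColor:
    return xyz_to_lab(spectrum_to_xyz(spectrum, ctx), ctx)


def delta_e(c1: LabColor, c2: LabColor, method: str = "cie76") -> float:
    """Color difference between two CIELAB colors.

    ``cie76`` (default) is the Euclidean distance in Lab; ``ciede2000`` is
    available behind the flag for comparison work.
    """
    if method == "cie76":
        return float(np.linalg.norm(c1.as_array() - c2.as_array()))
    if method == "ciede2000":
        from skimage.color import deltaE_ciede2000

        return float(deltaE_ciede2000(c1.as_array(), c2.as_array()))
    raise ValidationError(f"unknown delta E method {method!r}")


def cube_to_lab(cube: ReflectanceCube, ctx: ColorimetryContext) -> LabImage:
    """Per-pixel CIELAB image of a reflectance cube.

    Vectorised: the band→grid resampling and the tristimulus quadrature
    compose into one (3, bands) matrix applied to every pixel; results are
    identical (to floating tolerance) to looping spectrum_to_xyz/xyz_to_lab
    over pixels.
    """
    mat = ctx.resample_matrix(cube.axis.wavelengths_nm)
    op = ctx.weights.T @ mat  # (3, bands)
    bands, rows, cols = cube.shape
    xyz = op @ cube.values.reshape(bands, rows * cols)  # (3, npix)
    f = _lab_f(xyz / np.asarray(ctx.white_point)[:, None])
    L = (116.0 * f[1] - 16.0).reshape(rows, cols)
    a = (500.0 * (f[0] - f[1])).reshape(rows, cols)
    b = (200.0 * (f[1] - f[2])).reshape(rows, cols)
    return LabImage(L, a, b, context_id=ctx.context_id)


# sRGB (IEC 61966-2-1) D65 primaries; XYZ scaled so that Y=1 is white.
# Rows are renormalised so the white point maps to RGB (1, 1, 1) exactly,
# keeping the neutral Lab axis on the gray axis after 8-bit rounding.
_SRGB_WHITE = np.array([0.95047, 1.0, 1.08883])
_XYZ_TO_SRGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)
_XYZ_TO_SRGB /= (_XYZ_TO_SRGB @ _SRGB_WHITE)[:, None]


def _srgb_encode(linear: np.ndarray) -> np.ndarray:
    linear = np.clip(linear, 0.0, 1.0)
    return np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.power(linear, 1.0 / 2.4) - 0.055,
    )


def lab_to_srgb(image: LabImage) -> np.ndarray:
    """8-bit sRGB array (rows, cols, 3) for a Lab image.

    The neutral Lab axis maps onto the sRGB D65 gray axis, so (100, 0, 0)
    renders pure white. Out-of-gamut channels clip; the clipped-pixel
    fraction is logged.
    """
    import logging

    fy = (image.L + 16.0) / 116.0
    fx = fy + image.a / 500.0
    fz = fy - image.b / 200.0
    xyz = np.stack([_lab_f_inv(fx), _lab_f_inv(fy), _lab_f_inv(fz)])
    xyz *= _SRGB_WHITE[:, None, None]
    linear = np.einsum("ij,jrc->irc", _XYZ_TO_SRGB, xyz)
    clipped = np.any((linear < 0) | (linear > 1), axis=0)
    frac = float(np.count_nonzero(clipped)) / clipped.size
    if frac > 0:
        logging.getLogger(__name__).info(
            "lab_to_srgb: %.2f%% of pixels clipped to gamut", 100 * frac
        )
    srgb = _srgb_encode(linear)
    out = np.rint(srgb * 255.0).astype(np.uint8)
    return np.moveaxis(out, 0, -1)


def lab_to_srgb_png(image: LabImage, path) -> None:
    """Render a Lab image to an 8-bit PNG file."""
    from PIL import Image

    Image.fromarray(lab_to_srgb(image), mode="RGB").save(path, format="PNG")
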