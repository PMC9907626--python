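"""File formats: ENVI band-sequential cubes, a compressed .npz container,
and the CSV interchange formats (spectra, landmarks, effects).

The ENVI dialect is deliberately narrow: band-sequential interleave only,
float32 or float64 data, wavelengths required in the header. Tidy CSV with
explicit column names is the single interchange format between pipeline
stages.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .roi import LandmarkSet
from .spectral import ReflectanceCube, ReflectanceSpectrum, SpectralAxis

logger = logging.getLogger(__name__)

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


# ---------------------------------------------------------------------------
# ENVI header + band-sequential binary


def write_envi(cube: ReflectanceCube, stem: str | Path) -> tuple[Path, Path]:
    """Write a cube as ``<stem>.hdr`` + ``<stem>.img`` (BSQ, float32)."""
    stem = Path(stem)
    hdr, img = stem.with_suffix(".hdr"), stem.with_suffix(".img")
    bands, lines, samples = cube.shape
    wl = ", ".join(f"{v:g}" for v in cube.axis.wavelengths_nm)
    hdr.write_text(
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"fwhm = {cube.axis.bandwidth_fwhm_nm:g}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    cube.values.astype(np.float32).tofile(img)
    return hdr, img


def _parse_envi_header(path: Path) -> dict:
    text = path.read_text()
    if not text.lstrip().startswith("ENVI"):
        raise FormatError(f"{path}: not an ENVI header")
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for line in text.splitlines()[1:]:
        if in_braces:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_braces, key, buf = False, None, []
            continue
        if "=" not in line:
            continue
        k, v = (s.strip() for s in line.split("=", 1))
        if "{" in v and "}" not in v:
            key, buf, in_braces = k.lower(), [v], True
        else:
            fields[k.lower()] = v
    if in_braces:
        raise FormatError(f"{path}: unterminated brace list for field {key!r}")
    return fields


def read_envi(stem: str | Path) -> ReflectanceCube:
    """Read an ENVI cube written by this package or a compatible writer."""
    stem = Path(stem)
    hdr_path = stem if stem.suffix == ".hdr" else stem.with_suffix(".hdr")
    fields = _parse_envi_header(hdr_path)
    for required in ("samples", "lines", "bands", "data type", "interleave",
                     "wavelength"):
        if required not in fields:
            raise FormatError(f"{hdr_path}: missing header field {required!r}")
    if fields["interleave"].lower() != "bsq":
        raise FormatError(
            f"{hdr_path}: only band-sequential (bsq) interleave is supported, "
            f"got {fields['interleave']!r}"
        )
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise FormatError(f"{hdr_path}: unsupported data type code {code}")
    samples, lines, bands = (
        int(fields[k]) for k in ("samples", "lines", "bands")
    )
    wl = np.array(
        [float(tok) for tok in
         fields["wavelength"].strip().strip("{}").replace(",", " ").split()]
    )
    if wl.size != bands:
        raise FormatError(
            f"{hdr_path}: field 'wavelength' lists {wl.size} values but "
            f"'bands' = {bands}"
        )
    fwhm = float(fields.get("fwhm", 32))
    img_path = hdr_path.with_suffix(".img")
    if not img_path.exists():
        img_path = hdr_path.with_suffix("")
    data = np.fromfile(img_path, dtype=_ENVI_DTYPES[code])
    expected = bands * lines * samples
    if data.size != expected:
        raise FormatError(
            f"{img_path}: holds {data.size} values, header implies {expected}"
        )
    values = data.reshape(bands, lines, samples).astype(float)
    return ReflectanceCube(values, SpectralAxis(wl, fwhm), {"source": str(hdr_path)})


# ---------------------------------------------------------------------------
# compressed single-file container


def write_cube(cube: ReflectanceCube, path: str | Path) -> None:
    """Lossless compressed container (.npz) for a reflectance cube."""
    import json

    np.savez_compressed(
        path,
        values=cube.values,
        wavelengths_nm=cube.axis.wavelengths_nm,
        bandwidth_fwhm_nm=cube.axis.bandwidth_fwhm_nm,
        provenance=json.dumps(cube.provenance),
    )


def read_cube(path: str | Path) -> ReflectanceCube:
    import json

    try:
        with np.load(path, allow_pickle=False) as npz:
            values = npz["values"]
            axis = SpectralAxis(
                npz["wavelengths_nm"], float(npz["bandwidth_fwhm_nm"])
            )
            provenance = json.loads(str(npz["provenance"]))
    except KeyError as exc:
        raise FormatError(f"{path}: missing container field {exc}") from exc
    return ReflectanceCube(values, axis, provenance)


def load_cube(path: str | Path) -> ReflectanceCube:
    """Read a cube from either container (.npz) or ENVI (.hdr) format."""
    path = Path(path)
    if path.suffix == ".npz":
        return read_cube(path)
    return read_envi(path)


# ---------------------------------------------------------------------------
# CSV formats


def write_spectrum_csv(spectrum: ReflectanceSpectrum, path: str | Path) -> None:
    """Two-column CSV ``wavelength_nm,reflectance`` (fractions)."""
    df = pd.DataFrame({
        "wavelength_nm": spectrum.wavelengths_nm,
        "reflectance": spectrum.reflectance,
    })
    if spectrum.sigma is not None:
        df["sigma"] = spectrum.sigma
    df.to_csv(path, index=False, float_format="%.8g")


def read_spectrum_csv(path: str | Path) -> ReflectanceSpectrum:
    """Read a spectrum CSV; percent-scale reflectance (values above 1.5)
    is divided by 100 with a logged warning."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise FormatError(f"{path}: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    if "wavelength_nm" not in cols or "reflectance" not in cols:
        raise FormatError(
            f"{path}: header must name columns 'wavelength_nm,reflectance'"
        )
    df.columns = cols
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    refl = df["reflectance"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise FormatError(f"{path}: wavelengths must be strictly increasing")
    if np.nanmax(refl) > 1.5:
        logger.warning("%s: reflectance looks percent-scaled; dividing by 100", path)
        refl = refl / 100.0
    sigma = df["sigma"].to_numpy(dtype=float) if "sigma" in cols else None
    return ReflectanceSpectrum(wl, refl, sigma)


def write_landmarks_csv(landmarks: LandmarkSet, path: str | Path) -> None:
    pd.DataFrame({
        "index": np.arange(landmarks.points.shape[0]),
        "row": landmarks.points[:, 0],
        "col": landmarks.points[:, 1],
    }).to_csv(path, index=False, float_format="%.4f")


def read_landmarks_csv(path: str | Path) -> LandmarkSet:
    df = pd.read_csv(path)
    if list(df.columns) != ["index", "row", "col"]:
        raise FormatError(f"{path}: expected columns index,row,col")
    df = df.sort_values("index")
    return LandmarkSet(df[["row", "col"]].to_numpy(dtype=float), source="fixture")


def write_effects_csv(effects: pd.DataFrame, path: str | Path) -> None:
    effects.to_csv(path, index=False, float_format="%.6g")


def read_effects_csv(path: str | Path) -> pd.DataFrame:
    from .study import REQUIRED_EFFECT_COLUMNS

    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_EFFECT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing effect columns {missing}")
    return df
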