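"""Synthetic skin spectra, datacubes, landmarks, and full screening studies
with known ground truth.

No panel data are deposited with the study this package operationalises, so
every pipeline stage is exercised against a generator that emulates the
relevant features of the real data: smooth skin-like reflectance over
420-730 nm (a melanin-like monotone rise plus hemoglobin-like dips near 545
and 575 nm), product-induced CIELAB shifts of realistic magnitude
implemented as smooth spectral modulations, ~2% multiplicative band noise,
and a schematic 68-landmark face layout for ROI placement. All randomness
flows through a seeded generator, so identical configuration and seed give
identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .colorimetry import ColorimetryContext, LabColor, spectrum_to_lab
from .errors import ConvergenceError, ValidationError
from .roi import N_LANDMARKS, LandmarkSet
from .spectral import (
    CalibrationSet,
    RawFrame,
    ReflectanceCube,
    ReflectanceSpectrum,
    SpectralAxis,
)
from .uncertainty import NoiseModel


# ---------------------------------------------------------------------------
# skin spectra


@dataclass(frozen=True)
class SkinSpectrumParams:
    """Parameters of the smooth skin reflectance model.

    ``baseline`` sets the blue-end reflectance level; ``slope`` the
    melanin-like monotone rise toward the red end (a logistic ramp centered
    near 560 nm); ``dip_545``/``dip_575`` the depths of the hemoglobin-like
    absorption dips. Defaults give a mid skin tone (L* ~ 60, a* ~ 13,
    b* ~ 18 under D65/10-degree).
    """

    baseline: float = 0.22
    slope: float = 0.38
    dip_545: float = 0.05
    dip_575: float = 0.04
    dip_width_nm: float = 14.0

    def vary(self, rng: np.random.Generator) -> "SkinSpectrumParams":
        """Per-model variation of the defaults (a realistic panel spread)."""
        return replace(
            self,
            baseline=self.baseline + rng.uniform(-0.04, 0.04),
            slope=self.slope + rng.uniform(-0.08, 0.08),
            dip_545=self.dip_545 + rng.uniform(-0.015, 0.015),
            dip_575=self.dip_575 + rng.uniform(-0.012, 0.012),
        )


def make_skin_spectrum(
    params: SkinSpectrumParams, axis: SpectralAxis | None = None
) -> ReflectanceSpectrum:
    """Smooth skin-like reflectance spectrum on a spectral axis."""
    axis = axis or SpectralAxis.standard()
    wl = axis.wavelengths_nm
    ramp = 1.0 / (1.0 + np.exp(-(wl - 560.0) / 40.0))
    refl = (
        params.baseline
        + params.slope * ramp
        - params.dip_545 * np.exp(-0.5 * ((wl - 545.0) / params.dip_width_nm) ** 2)
        - params.dip_575 * np.exp(-0.5 * ((wl - 575.0) / params.dip_width_nm) ** 2)
    )
    if np.any(refl <= 0) or np.any(refl >= 1):
        raise ValidationError("parameters drive reflectance out of (0, 1)")
    return ReflectanceSpectrum(wl.copy(), refl)


# ---------------------------------------------------------------------------
# product effects as spectral modulations


@dataclass(frozen=True)
class ProductEffect:
    """Target CIELAB shift (dL, da, db) a product induces on skin."""

    name: str
    target: tuple[float, float, float]

    @classmethod
    def defaults(cls) -> dict[str, "ProductEffect"]:
        """Three foundation-like products spanning realistic effect sizes:
        a light-coverage product (A), a strongly brightening one (B), and an
        intermediate mattifying one (C)."""
        return {
            "A": cls("A", (0.3, -0.25, 1.1)),
            "B": cls("B", (3.9, -2.1, -1.2)),
            "C": cls("C", (1.5, -1.5, -2.2)),
        }


def _effect_basis(wl: np.ndarray) -> np.ndarray:
    """Three smooth spectral modes spanning the L*/a*/b* directions:
    a flat lift, a blue-yellow ramp, and a green-band bump."""
    return np.stack([
        np.ones_like(wl),
        (wl - 575.0) / 155.0,
        np.exp(-0.5 * ((wl - 550.0) / 30.0) ** 2),
    ])


def apply_product_effect(
    spectrum: ReflectanceSpectrum,
    effect: ProductEffect,
    ctx: ColorimetryContext | None = None,
    tol: float = 0.2,
) -> ReflectanceSpectrum:
    """Modulate a spectrum so its Lab shifts by the effect target.

    A three-coefficient expansion over smooth spectral modes is solved by
    least squares so the achieved Lab shift lands within ``tol`` CIELAB
    units of the target per channel; targets that would push reflectance
    out of (0, 1) raise :class:`ConvergenceError`.
    """
    ctx = ctx or ColorimetryContext()
    wl = spectrum.wavelengths_nm
    basis = _effect_basis(wl)
    lab0 = spectrum_to_lab(spectrum, ctx).as_array()
    target = np.asarray(effect.target, dtype=float)

    def residual(c: np.ndarray) -> np.ndarray:
        refl = np.clip(spectrum.reflectance + c @ basis, 1e-6, 0.999)
        lab = spectrum_to_lab(
            ReflectanceSpectrum(wl, refl), ctx
        ).as_array()
        return lab - lab0 - target

    sol = least_squares(residual, np.zeros(3), xtol=1e-12, ftol=1e-12)
    refl = spectrum.reflectance + sol.x @ basis
    if np.any(refl <= 0) or np.any(refl >= 1):
        raise ConvergenceError(
            f"effect {effect.target} drives reflectance out of (0, 1)"
        )
    achieved = spectrum_to_lab(ReflectanceSpectrum(wl, refl), ctx).as_array()
    if np.any(np.abs(achieved - lab0 - target) > tol):
        raise ConvergenceError(
            f"effect target {tuple(target)} unreachable: achieved "
            f"{tuple(np.round(achieved - lab0, 3))}"
        )
    return ReflectanceSpectrum(wl, refl)


# ---------------------------------------------------------------------------
# face scene and datacube


def make_face_landmarks(image_shape: tuple[int, int]) -> LandmarkSet:
    """Schematic 68-point landmark layout (iBUG numbering) for a face that
    fills the frame: jaw 0-16, brows 17-26, nose 27-35, eyes 36-47,
    mouth 48-67. Image-left is the subject's right side."""
    h, w = image_shape
    cr, cc = 0.47 * h, 0.5 * w
    ar, ac = 0.45 * h, 0.42 * w
    pts = np.zeros((N_LANDMARKS, 2))
    t = np.arange(17) * np.pi / 16.0
    pts[0:17, 0] = cr + ar * np.sin(t)
    pts[0:17, 1] = cc - ac * np.cos(t)
    for side, base in ((-1, 17), (1, 22)):
        xs = np.linspace(0.15, 0.65, 5) * side
        pts[base:base + 5, 0] = cr - 0.42 * ar + 0.08 * ar * np.abs(xs) / 0.65
        pts[base:base + 5, 1] = cc + ac * xs
    pts[27:31, 0] = cr + ar * np.linspace(-0.30, 0.10, 4)
    pts[27:31, 1] = cc
    pts[31:36, 0] = cr + 0.18 * ar
    pts[31:36, 1] = cc + ac * np.linspace(-0.15, 0.15, 5)
    for base, xoff in ((36, -0.40), (42, 0.40)):
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        pts[base:base + 6, 0] = cr - 0.25 * ar + 0.05 * ar * np.sin(ang)
        pts[base:base + 6, 1] = cc + ac * xoff + 0.12 * ac * np.cos(ang)
    ang = np.linspace(0, 2 * np.pi, 20, endpoint=False)
    pts[48:68, 0] = cr + 0.55 * ar + 0.08 * ar * np.sin(ang)
    pts[48:68, 1] = cc + 0.28 * ac * np.cos(ang)
    pts[:, 0] = np.clip(pts[:, 0], 0, h - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, w - 1)
    return LandmarkSet(pts, source="fixture")


def make_face_mask(image_shape: tuple[int, int], dilation: float = 1.35) -> np.ndarray:
    """Elliptical face mask; dilated beyond the landmark hull so ROIs anchored
    on cheek landmarks stay on skin."""
    h, w = image_shape
    cr, cc = 0.47 * h, 0.5 * w
    ar, ac = 0.45 * h * dilation, 0.42 * w * dilation
    rows, cols = np.ogrid[:h, :w]
    return ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0


@dataclass
class SyntheticScene:
    """One face acquisition: skin and background spectra on a face template."""

    skin: ReflectanceSpectrum
    shape: tuple[int, int, int] = (31, 256, 256)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    background_scale: float = 0.45

    def __post_init__(self) -> None:
        if self.shape[0] != self.skin.wavelengths_nm.size:
            raise ValidationError("scene band count must match the skin spectrum")


def make_datacube(
    scene: SyntheticScene,
    with_raw: bool = False,
    quantize: bool = False,
) -> tuple[ReflectanceCube, LandmarkSet] | tuple[
    ReflectanceCube, LandmarkSet, list[RawFrame], CalibrationSet
]:
    """Render a scene into a noisy reflectance cube plus its landmarks.

    Per-voxel noise is multiplicative Gaussian with the scene's fractional
    sigma. With ``with_raw`` the cube is also inverse-rendered into raw
    count frames and a matching :class:`CalibrationSet` (dark frame,
    flat-field, white cube) so the calibration chain can be exercised
    end-to-end; ``quantize`` rounds those counts to integers for realism at
    the cost of quantization error.
    """
    bands, h, w = scene.shape
    axis = SpectralAxis(scene.skin.wavelengths_nm)
    rng = np.random.default_rng(scene.seed)
    mask = make_face_mask((h, w))
    landmarks = make_face_landmarks((h, w))

    clean = np.where(
        mask[None, :, :],
        scene.skin.reflectance[:, None, None],
        scene.background_scale * scene.skin.reflectance[:, None, None],
    )
    noisy = clean * (
        1.0 + scene.noise.fractional_sigma * rng.standard_normal(scene.shape)
    )
    np.clip(noisy, 0.0, 1.2, out=noisy)
    cube = ReflectanceCube(noisy, axis, {"seed": scene.seed, "synthetic": True})
    if not with_raw:
        return cube, landmarks

    dark = np.full((h, w), 100.0)
    flat = 1.0 + 0.05 * np.linspace(-1, 1, w)[None, :] * np.ones((h, 1))
    flat /= flat.mean()
    white_level = 20000.0 * (0.75 + 0.25 * np.sin(np.linspace(0, np.pi, bands)))
    white_cube = dark[None] + white_level[:, None, None] * flat[None]
    sample = dark[None] + (noisy / 0.99) * white_level[:, None, None] * flat[None]
    if quantize:
        sample, white_cube, dark = (
            np.rint(sample), np.rint(white_cube), np.rint(dark)
        )
    frames = [
        RawFrame(sample[i], float(axis.wavelengths_nm[i])) for i in range(bands)
    ]
    calib = CalibrationSet(dark, flat, white_cube, 0.99)
    return cube, landmarks, frames, calib


# ---------------------------------------------------------------------------
# full study simulation


@dataclass(frozen=True)
class StudyNoise:
    """Variability knobs of the simulated study, in the units of the data.

    ``spectral_sigma``: fractional per-voxel band noise (instrument SNR).
    ``model_effect_sd``: CIELAB SD of the per-model deviation from the
    product's target effect (what drives the SDs of the effect summaries).
    ``repetition_effect_sd``: CIELAB SD of the per-repetition drift of the
    effect (test repeatability). ``baseline_drift_sd``: CIELAB SD of the
    per-model-repetition baseline drift (cancels in the time difference).
    ``landmark_jitter_px``: SD of per-image landmark jitter (operator
    reproducibility via ROI placement); draws clip at 2 SD so synthetic
    ROIs stay on skin.
    """

    spectral_sigma: float = 0.02
    model_effect_sd: float = 0.9
    repetition_effect_sd: float = 0.3
    baseline_drift_sd: float = 0.3
    landmark_jitter_px: float = 2.0


@dataclass
class StudyResult:
    effects: "pd.DataFrame"
    measurements: "pd.DataFrame"
    ground_truth: dict


def simulate_study(
    design=None,
    effects: dict[str, ProductEffect] | None = None,
    seed: int = 0,
    shape: tuple[int, int, int] = (31, 64, 64),
    noise: StudyNoise | None = None,
    roi_size: tuple[int, int] | None = None,
    ctx: ColorimetryContext | None = None,
    out_dir=None,
) -> StudyResult:
    """Simulate the full screening study on the imager and measure it.

    One cube is generated per model-product-time point-repetition-operator
    session and pushed through the real analysis chain (landmarks → ROI →
    Lab → ROI statistics → time difference), yielding the tidy effect table
    alongside the injected ground truth. The ROI defaults to 75 x 75 pixels
    at full desk scale (256 px frames) and scales to a quarter of the frame
    for smaller smoke-test cubes.
    """
    import pandas as pd

    from .roi import (
        FixtureBackend,
        ROIDefinition,
        detect_landmarks,
        extract_roi_stats,
        resolve_roi,
        roi_difference,
    )
    from .colorimetry import cube_to_lab
    from .study import StudyDesign

    design = design or StudyDesign()
    effects = effects or ProductEffect.defaults()
    if set(effects) != set(design.products):
        raise ValidationError("effects must cover exactly the design products")
    noise = noise or StudyNoise()
    ctx = ctx or ColorimetryContext()
    bands, h, w = shape
    if roi_size is None:
        side = 75 if min(h, w) >= 256 else max(2, round(0.25 * min(h, w)))
        roi_size = (side, side)
    roi_def = ROIDefinition.right_cheek(roi_size)
    axis = SpectralAxis(np.linspace(420.0, 730.0, bands))
    root = np.random.default_rng(seed)
    noise_model = NoiseModel(noise.spectral_sigma)

    # per-model skin, per-(model, rep) baseline drift, per-(model, product,
    # rep) realized effect — all solved as spectral modulations once
    model_ids = [f"M{i + 1}" for i in range(design.n_models)]
    base_params = {
        m: SkinSpectrumParams().vary(root) for m in model_ids
    }
    base_spec = {m: make_skin_spectrum(base_params[m], axis) for m in model_ids}

    t0_spec: dict[tuple, ReflectanceSpectrum] = {}
    timm_spec: dict[tuple, ReflectanceSpectrum] = {}
    truth_rows = []
    for m in model_ids:
        # the per-model product response persists across repetitions; only a
        # smaller per-repetition drift of the effect changes between tests
        model_dev = {
            prod: root.normal(0.0, noise.model_effect_sd, 3)
            for prod in design.products
        }
        for rep in range(1, design.n_repetitions + 1):
            drift = root.normal(0.0, noise.baseline_drift_sd, 3)
            t0 = apply_product_effect(
                base_spec[m], ProductEffect("drift", tuple(drift)), ctx
            )
            t0_spec[(m, rep)] = t0
            for prod in design.products:
                realized = (
                    np.asarray(effects[prod].target)
                    + model_dev[prod]
                    + root.normal(0.0, noise.repetition_effect_sd, 3)
                )
                timm_spec[(m, prod, rep)] = apply_product_effect(
                    t0, ProductEffect(prod, tuple(realized)), ctx,
                    tol=0.2,
                )
                truth_rows.append(
                    {"model": m, "product": prod, "repetition": rep,
                     "true_dL": realized[0], "true_da": realized[1],
                     "true_db": realized[2]}
                )

    jitter_clip = 2.0 * noise.landmark_jitter_px
    effect_rows, meas_rows = [], []
    session_idx = 0
    for m in model_ids:
        for prod in design.products:
            for rep in range(1, design.n_repetitions + 1):
                for op in design.operators:
                    stats_by_tp = {}
                    for tp, spec in (
                        ("T0", t0_spec[(m, rep)]),
                        ("Timm", timm_spec[(m, prod, rep)]),
                    ):
                        scene = SyntheticScene(
                            skin=spec, shape=shape, noise=noise_model,
                            seed=int(root.integers(0, 2**31 - 1)),
                        )
                        cube, landmarks = make_datacube(scene)
                        jitter = np.clip(
                            np.random.default_rng(scene.seed + 1).normal(
                                0.0, noise.landmark_jitter_px,
                                landmarks.points.shape,
                            ),
                            -jitter_clip, jitter_clip,
                        )
                        jittered = LandmarkSet(
                            np.clip(
                                landmarks.points + jitter,
                                0, [[h - 1, w - 1]],
                            ),
                            source="fixture",
                        )
                        detected = detect_landmarks(
                            cube.values[0], FixtureBackend(jittered)
                        )
                        rect = resolve_roi(detected, roi_def, (h, w))
                        lab = cube_to_lab(cube, ctx)
                        st = extract_roi_stats(lab, rect, name=roi_def.name)
                        stats_by_tp[tp] = st
                        if out_dir is not None:
                            from .io import write_cube, write_landmarks_csv

                            stem = f"{m}_{prod}_rep{rep}_{op}_{tp}"
                            write_cube(cube, f"{out_dir}/{stem}.npz")
                            write_landmarks_csv(
                                detected, f"{out_dir}/{stem}_landmarks.csv"
                            )
                        meas_rows.append({
                            "model": m, "product": prod, "repetition": rep,
                            "operator": op, "instrument": "HSI",
                            "time_point": tp,
                            "L": st.mean_color.L_star,
                            "a": st.mean_color.a_star,
                            "b": st.mean_color.b_star,
                        })
                    shift = roi_difference(stats_by_tp["T0"], stats_by_tp["Timm"])
                    effect_rows.append({
                        "model": m, "product": prod, "repetition": rep,
                        "operator": op, "instrument": "HSI",
                        "dL": shift.dL, "da": shift.da, "db": shift.db,
                        "dE": shift.dE,
                    })
                    session_idx += 1

    truth = {
        "seed": seed,
        "targets": {p: list(e.target) for p, e in effects.items()},
        "per_session": truth_rows,
    }
    if out_dir is not None:
        import json
        from pathlib import Path

        Path(out_dir, "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return StudyResult(
        pd.DataFrame(effect_rows), pd.DataFrame(meas_rows), truth
    )
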