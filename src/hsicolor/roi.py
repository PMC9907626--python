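"""Landmark-anchored regions of interest and per-ROI color statistics.

ROIs are rectangles placed relative to a 68-point facial landmark set (the
standard iBUG annotation scheme). Detection is a pluggable backend so the
pipeline runs identically on synthetic fixtures (stored landmarks) and, if
a detector is available, on real images. The default study ROI is a
75 x 75 pixel square on the right cheek (12 x 12 mm at the instrument's
160 um pixel pitch), anchored on the centroid of a configurable landmark
triple.

Pixel coordinates are 0-based, row-major, origin top-left; rectangles are
half-open ``[r0, r0+h) x [c0, c0+w)``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .colorimetry import LabColor, LabImage, delta_e
from .errors import DetectionError, ValidationError

logger = logging.getLogger(__name__)

N_LANDMARKS = 68

#: Default anchor triples: jaw points plus a nose-wing point on each side
#: of the iBUG 68-point scheme (image-left = subject's right cheek).
RIGHT_CHEEK_ANCHORS = (2, 4, 31)
LEFT_CHEEK_ANCHORS = (12, 14, 35)


@dataclass(frozen=True)
class LandmarkSet:
    """Exactly 68 (row, col) facial landmark points."""

    points: np.ndarray
    source: str = "fixture"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValidationError(
                f"expected {N_LANDMARKS} (row, col) points, got {pts.shape}"
            )

    def validate_bounds(self, image_shape: tuple[int, int]) -> None:
        h, w = image_shape
        rows, cols = self.points[:, 0], self.points[:, 1]
        if np.any(rows < 0) or np.any(rows >= h) or np.any(cols < 0) or np.any(cols >= w):
            raise ValidationError("landmarks fall outside the image bounds")

    def shifted(self, dr: float, dc: float) -> "LandmarkSet":
        return LandmarkSet(self.points + np.array([dr, dc]), self.source)


class LandmarkBackend(Protocol):
    def detect(self, image: np.ndarray) -> LandmarkSet: ...


class FixtureBackend:
    """Deterministic backend returning stored landmarks (synthetic scenes)."""

    def __init__(self, landmarks: LandmarkSet):
        self._landmarks = landmarks

    def detect(self, image: np.ndarray) -> LandmarkSet:
        return LandmarkSet(self._landmarks.points.copy(), source="fixture")


def detect_landmarks(image: np.ndarray, backend: LandmarkBackend) -> LandmarkSet:
    """Locate the 68 facial landmarks on an image via the given backend."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValidationError("image is empty")
    result = backend.detect(image)
    if result is None:
        raise DetectionError("no face found")
    result.validate_bounds(image.shape[:2])
    return result


@dataclass(frozen=True)
class ROIDefinition:
    """A named rectangle anchored on the centroid of landmark indices."""

    name: str
    anchor_indices: tuple[int, ...] = RIGHT_CHEEK_ANCHORS
    size_px: tuple[int, int] = (75, 75)

    def __post_init__(self) -> None:
        h, w = self.size_px
        if h < 1 or w < 1:
            raise ValidationError("ROI size must be positive")
        if not all(0 <= i < N_LANDMARKS for i in self.anchor_indices):
            raise ValidationError("anchor indices must be valid landmark indices")

    @classmethod
    def right_cheek(cls, size_px: tuple[int, int] = (75, 75)) -> "ROIDefinition":
        return cls("Right_Cheek", RIGHT_CHEEK_ANCHORS, size_px)

    @classmethod
    def left_cheek(cls, size_px: tuple[int, int] = (75, 75)) -> "ROIDefinition":
        return cls("Left_Cheek", LEFT_CHEEK_ANCHORS, size_px)


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle [r0, r0+h) x [c0, c0+w)."""

    r0: int
    c0: int
    height: int
    width: int

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.r0, self.r0 + self.height), slice(self.c0, self.c0 + self.width)

    @property
    def n_pixels(self) -> int:
        return self.height * self.width


def resolve_roi(
    landmarks: LandmarkSet,
    definition: ROIDefinition,
    image_shape: tuple[int, int],
) -> Rect:
    """Place the ROI rectangle centered on its landmark anchor.

    The rectangle is centered on the centroid of the anchor landmarks
    (top-left corner at ``round(anchor) - size // 2``) and shifted inward
    if it would cross an image edge; the shift is logged.
    """
    h, w = definition.size_px
    img_h, img_w = image_shape
    if h > img_h or w > img_w:
        raise ValidationError(
            f"image {image_shape} smaller than ROI {definition.size_px}"
        )
    anchor = landmarks.points[list(definition.anchor_indices)].mean(axis=0)
    r0 = int(round(anchor[0])) - h // 2
    c0 = int(round(anchor[1])) - w // 2
    r0c, c0c = np.clip(r0, 0, img_h - h), np.clip(c0, 0, img_w - w)
    if (r0c, c0c) != (r0, c0):
        logger.info(
            "resolve_roi: %s shifted inward by (%d, %d) at the image edge",
            definition.name, r0c - r0, c0c - c0,
        )
    return Rect(int(r0c), int(c0c), h, w)


@dataclass
class ChannelStats:
    mean: float
    sd: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray


@dataclass
class ROIStats:
    """Per-channel mean/SD/histogram of L*, a*, b* over one ROI."""

    name: str
    rect: Rect
    channels: dict[str, ChannelStats]
    n_pixels: int

    @property
    def mean_color(self) -> LabColor:
        return LabColor(
            self.channels["L"].mean,
            self.channels["a"].mean,
            self.channels["b"].mean,
        )


def extract_roi_stats(
    lab: LabImage,
    rect: Rect,
    name: str = "",
    bins: int = 64,
    hist_ranges: dict[str, tuple[float, float]] | None = None,
) -> ROIStats:
    """Channel means, sample SDs, and histograms over a rectangle.

    ``hist_ranges`` fixes the histogram edges per channel so paired
    before/after extractions share a scale; by default each channel spans
    its own min/max (a degenerate constant channel gets a unit-wide bin).
    """
    rs, cs = rect.slices
    if (
        rect.r0 < 0 or rect.c0 < 0
        or rect.r0 + rect.height > lab.shape[0]
        or rect.c0 + rect.width > lab.shape[1]
    ):
        raise ValidationError(f"rectangle {rect} lies outside image {lab.shape}")
    channels = {}
    for key, plane in (("L", lab.L), ("a", lab.a), ("b", lab.b)):
        vals = plane[rs, cs].ravel()
        if hist_ranges and key in hist_ranges:
            lo, hi = hist_ranges[key]
        else:
            lo, hi = float(vals.min()), float(vals.max())
            if lo == hi:
                lo, hi = lo - 0.5, hi + 0.5
        counts, edges = np.histogram(vals, bins=bins, range=(lo, hi))
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        channels[key] = ChannelStats(float(vals.mean()), sd, counts, edges)
    return ROIStats(name, rect, channels, rect.n_pixels)


def shared_hist_ranges(lab_pair: Sequence[LabImage], rect_pair: Sequence[Rect]) -> dict:
    """Pooled per-channel (min, max) across a before/after pair of ROIs."""
    ranges: dict[str, tuple[float, float]] = {}
    for key in ("L", "a", "b"):
        lo, hi = np.inf, -np.inf
        for lab, rect in zip(lab_pair, rect_pair):
            plane = {"L": lab.L, "a": lab.a, "b": lab.b}[key]
            vals = plane[rect.slices]
            lo, hi = min(lo, float(vals.min())), max(hi, float(vals.max()))
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        ranges[key] = (lo, hi)
    return ranges


@dataclass(frozen=True)
class ColorShift:
    """Before-to-after change in ROI mean color (T_imm minus T_0)."""

    dL: float
    da: float
    db: float
    dE: float
    roi_name: str = ""


def roi_difference(before: ROIStats, after: ROIStats) -> ColorShift:
    """Change in ROI mean color between two time points of the same ROI."""
    if before.name != after.name or before.rect.height != after.rect.height \
            or before.rect.width != after.rect.width:
        raise ValidationError(
            f"ROI identity mismatch: {before.name}/{before.rect} vs "
            f"{after.name}/{after.rect}"
        )
    c0, c1 = before.mean_color, after.mean_color
    return ColorShift(
        c1.L_star - c0.L_star,
        c1.a_star - c0.a_star,
        c1.b_star - c0.b_star,
        delta_e(c0, c1),
        roi_name=before.name,
    )


def pixel_pitch(physical_size_mm: float, pixels: int) -> float:
    """Micrometres per pixel for a physical ROI edge length.

    The 12 mm cheek ROI over 75 pixels gives the instrument's 160 um pitch.
    """
    if pixels < 1:
        raise ValidationError("pixel count must be >= 1")
    if physical_size_mm <= 0:
        raise ValidationError("physical size must be positive")
    return 1000.0 * physical_size_mm / pixels
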