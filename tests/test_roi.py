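import numpy as np
import pytest

from hsicolor import (
    LandmarkSet,
    ROIDefinition,
    Rect,
    ReflectanceCube,
    ValidationError,
    cube_to_lab,
    detect_landmarks,
    extract_roi_stats,
    pixel_pitch,
    resolve_roi,
    roi_difference,
)
from hsicolor.colorimetry import LabImage
from hsicolor.roi import FixtureBackend, shared_hist_ranges


def landmarks_at(anchor_row, anchor_col, image_shape=(512, 512)):
    """68 landmarks whose (2, 4, 31) centroid sits exactly at the anchor."""
    pts = np.tile([anchor_row, anchor_col], (68, 1)).astype(float)
    return LandmarkSet(np.clip(pts, 0, np.array(image_shape) - 1))


def uniform_lab(shape, L=60.0, a=12.0, b=18.0):
    return LabImage(np.full(shape, L), np.full(shape, a), np.full(shape, b))


class TestLandmarks:
    def test_fixture_backend_is_verbatim_and_deterministic(self, rng):
        pts = rng.uniform(10, 90, (68, 2))
        backend = FixtureBackend(LandmarkSet(pts))
        image = np.zeros((100, 100))
        first = detect_landmarks(image, backend)
        second = detect_landmarks(image, backend)
        assert np.array_equal(first.points, pts)
        assert np.array_equal(first.points, second.points)

    def test_out_of_bounds_landmarks_rejected(self):
        pts = np.full((68, 2), 50.0)
        pts[10] = [200.0, 50.0]
        backend = FixtureBackend(LandmarkSet(pts))
        with pytest.raises(ValidationError):
            detect_landmarks(np.zeros((100, 100)), backend)

    def test_wrong_point_count_rejected(self):
        with pytest.raises(ValidationError):
            LandmarkSet(np.zeros((67, 2)))

    def test_empty_image_rejected(self):
        backend = FixtureBackend(LandmarkSet(np.full((68, 2), 1.0)))
        with pytest.raises(ValidationError):
            detect_landmarks(np.zeros((0, 0)), backend)


class TestResolveRoi:
    def test_centered_rectangle(self):
        rect = resolve_roi(
            landmarks_at(100, 100), ROIDefinition.right_cheek(), (512, 512)
        )
        assert (rect.r0, rect.c0) == (63, 63)
        assert (rect.height, rect.width) == (75, 75)

    def test_edge_collision_clamps_to_origin(self):
        rect = resolve_roi(
            landmarks_at(10, 10), ROIDefinition.right_cheek(), (512, 512)
        )
        assert (rect.r0, rect.c0) == (0, 0)

    def test_single_pixel_roi(self):
        definition = ROIDefinition("dot", (2, 4, 31), (1, 1))
        rect = resolve_roi(landmarks_at(5, 7), definition, (100, 100))
        assert rect.slices == (slice(5, 6), slice(7, 8))

    def test_image_smaller_than_roi_rejected(self):
        with pytest.raises(ValidationError):
            resolve_roi(
                landmarks_at(10, 10, (50, 50)), ROIDefinition.right_cheek(), (50, 50)
            )

    @pytest.mark.parametrize("dr,dc", [(7, 0), (0, -13), (21, 34)])
    def test_translation_equivariance(self, dr, dc):
        lm = landmarks_at(200, 200)
        base = resolve_roi(lm, ROIDefinition.right_cheek(), (512, 512))
        moved = resolve_roi(lm.shifted(dr, dc), ROIDefinition.right_cheek(), (512, 512))
        assert (moved.r0 - base.r0, moved.c0 - base.c0) == (dr, dc)


class TestRoiStats:
    def test_uniform_region(self):
        stats = extract_roi_stats(uniform_lab((100, 100)), Rect(10, 10, 20, 20))
        for ch in ("L", "a", "b"):
            assert stats.channels[ch].sd == 0.0
            assert np.count_nonzero(stats.channels[ch].hist_counts) == 1

    def test_standard_roi_pixel_count(self):
        stats = extract_roi_stats(uniform_lab((200, 200)), Rect(0, 0, 75, 75))
        assert stats.n_pixels == 75 * 75 == 5625

    def test_two_valued_region_mean_and_sample_sd(self):
        L = np.full((75, 150), 10.0)
        L[:, 75:] = 20.0
        lab = LabImage(L, np.zeros_like(L), np.zeros_like(L))
        stats = extract_roi_stats(lab, Rect(0, 38, 75, 75))
        # rect covers half 10s, half 20s (75x75 window straddling the split)
        vals = L[0:75, 38:113]
        assert stats.channels["L"].mean == pytest.approx(vals.mean())
        assert stats.channels["L"].sd == pytest.approx(vals.std(ddof=1))

    def test_half_and_half_matches_hand_value(self):
        # exactly half 10 / half 20 over 5625-1 pixels is impossible (odd n),
        # so use an even 50x50 region: sample SD = 5 * sqrt(n/(n-1))
        L = np.full((50, 50), 10.0)
        L[25:, :] = 20.0
        lab = LabImage(L, np.zeros_like(L), np.zeros_like(L))
        stats = extract_roi_stats(lab, Rect(0, 0, 50, 50))
        assert stats.channels["L"].mean == pytest.approx(15.0)
        assert stats.channels["L"].sd == pytest.approx(5.001, abs=1e-3)

    def test_histogram_conserves_pixel_count(self, rng):
        lab = LabImage(
            rng.normal(60, 3, (80, 80)),
            rng.normal(12, 2, (80, 80)),
            rng.normal(18, 2, (80, 80)),
        )
        stats = extract_roi_stats(lab, Rect(5, 9, 40, 33))
        for ch in ("L", "a", "b"):
            assert stats.channels[ch].hist_counts.sum() == stats.n_pixels

    def test_shared_edges_across_time_points(self, rng):
        before = LabImage(*rng.normal(60, 2, (3, 50, 50)))
        after = LabImage(*(rng.normal(63, 2, (3, 50, 50))))
        rect = Rect(10, 10, 30, 30)
        ranges = shared_hist_ranges([before, after], [rect, rect])
        s0 = extract_roi_stats(before, rect, hist_ranges=ranges)
        s1 = extract_roi_stats(after, rect, hist_ranges=ranges)
        for ch in ("L", "a", "b"):
            assert np.array_equal(s0.channels[ch].hist_edges, s1.channels[ch].hist_edges)
            assert s0.channels[ch].hist_counts.sum() == rect.n_pixels

    def test_rect_outside_image_rejected(self):
        with pytest.raises(ValidationError):
            extract_roi_stats(uniform_lab((50, 50)), Rect(30, 30, 30, 30))

    def test_mean_matches_naive_loop_over_cube(self, ctx, axis, rng):
        """ROI mean equals the mean of per-pixel Lab recomputed by loop."""
        from hsicolor import ReflectanceSpectrum, spectrum_to_lab

        values = np.clip(rng.uniform(0.1, 0.9, (31, 12, 12)), 0, 1)
        cube = ReflectanceCube(values, axis)
        lab = cube_to_lab(cube, ctx)
        rect = Rect(2, 3, 6, 7)
        stats = extract_roi_stats(lab, rect)
        acc = []
        for r in range(2, 8):
            for c in range(3, 10):
                spec = ReflectanceSpectrum(axis.wavelengths_nm, values[:, r, c])
                acc.append(spectrum_to_lab(spec, ctx).as_array())
        ref = np.mean(acc, axis=0)
        assert stats.channels["L"].mean == pytest.approx(ref[0], abs=1e-9)
        assert stats.channels["a"].mean == pytest.approx(ref[1], abs=1e-9)
        assert stats.channels["b"].mean == pytest.approx(ref[2], abs=1e-9)


class TestRoiDifference:
    def test_identical_stats_give_zero_shift(self):
        s = extract_roi_stats(uniform_lab((50, 50)), Rect(0, 0, 20, 20), name="Right_Cheek")
        shift = roi_difference(s, s)
        assert (shift.dL, shift.da, shift.db, shift.dE) == (0, 0, 0, 0)

    def test_three_four_five_shift(self):
        before = extract_roi_stats(
            uniform_lab((50, 50), 50, 0, 0), Rect(0, 0, 20, 20), name="R"
        )
        after = extract_roi_stats(
            uniform_lab((50, 50), 53, 0, 4), Rect(0, 0, 20, 20), name="R"
        )
        shift = roi_difference(before, after)
        assert shift.dL == pytest.approx(3.0)
        assert shift.db == pytest.approx(4.0)
        assert shift.dE == pytest.approx(5.0)

    def test_darkening_product_gives_negative_dL(self):
        before = extract_roi_stats(uniform_lab((50, 50), 60), Rect(0, 0, 10, 10), name="R")
        after = extract_roi_stats(uniform_lab((50, 50), 57), Rect(0, 0, 10, 10), name="R")
        assert roi_difference(before, after).dL < 0

    def test_mismatched_roi_identity_rejected(self):
        a = extract_roi_stats(uniform_lab((50, 50)), Rect(0, 0, 20, 20), name="Right_Cheek")
        b = extract_roi_stats(uniform_lab((50, 50)), Rect(0, 0, 20, 20), name="Left_Cheek")
        with pytest.raises(ValidationError):
            roi_difference(a, b)


class TestPixelPitch:
    def test_study_roi_pitch(self):
        assert pixel_pitch(12.0, 75) == pytest.approx(160.0)

    def test_unit_conversion(self):
        assert pixel_pitch(1.0, 1) == pytest.approx(1000.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            pixel_pitch(12.0, 0)
        with pytest.raises(ValidationError):
            pixel_pitch(0.0, 75)
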