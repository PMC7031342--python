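"""Segmentation chain: mean-threshold masks, outlines, axis, chord length."""

import numpy as np
import pytest
from skimage.draw import disk, ellipse as draw_ellipse

from cardioquant.segmentation import (
    AxisLine,
    DegenerateMaskError,
    ImageStack,
    SegmentationParams,
    binarize_frame,
    extract_outline,
    length_under_line,
    longest_axis,
    make_kymograph,
    smooth_outline,
    track_length,
)
from cardioquant.synthetic import CellMovieSpec, make_cell_movie


def _line_clip_chord(mask: np.ndarray, line: AxisLine) -> float:
    """Independent chord oracle: exact line/pixel-square clipping, first
    entry to last exit over every foreground pixel."""
    ys, xs = np.nonzero(mask)
    dx, dy = line.direction
    ax, ay = line.anchor
    tmin, tmax = np.inf, -np.inf
    for x, y in zip(xs, ys):
        t0, t1 = -np.inf, np.inf
        inside = True
        for d, o, c in ((dx, ax, x), (dy, ay, y)):
            if abs(d) < 1e-12:
                if not (c - 0.5 <= o <= c + 0.5):
                    inside = False
                    break
            else:
                ta, tb = (c - 0.5 - o) / d, (c + 0.5 - o) / d
                if ta > tb:
                    ta, tb = tb, ta
                t0, t1 = max(t0, ta), min(t1, tb)
        if inside and t0 <= t1:
            tmin, tmax = min(tmin, t0), max(tmax, t1)
    assert tmax > tmin, "oracle: line misses the mask"
    return tmax - tmin


class TestBinarize:
    def test_hand_computed_mean_threshold(self):
        frame = np.full((4, 4), 100.0)
        frame[0:3, 0:3] = 1000.0
        # mean = (9*1000 + 7*100)/16 = 606.25; only the block is above
        mask = binarize_frame(frame)
        expected = np.zeros((4, 4), bool)
        expected[0:3, 0:3] = True
        np.testing.assert_array_equal(mask, expected)

    def test_uniform_frame_is_degenerate(self):
        with pytest.raises(DegenerateMaskError):
            binarize_frame(np.full((8, 8), 7.0))

    def test_ellipse_mask_area(self, rest_frame):
        # fixture cell: 160 x 64 px ellipse -> semi-axes 80 and 32
        mask = binarize_frame(rest_frame)
        assert mask.sum() == pytest.approx(np.pi * 80 * 32, rel=0.02)

    def test_keeps_largest_component_and_fills_holes(self):
        frame = np.zeros((32, 32))
        frame[4:20, 4:20] = 1000.0
        frame[10:12, 10:12] = 0.0  # interior hole
        frame[28, 28] = 1000.0  # speck
        mask = binarize_frame(frame)
        assert mask[10, 10] and mask[11, 11]  # hole filled
        assert not mask[28, 28]  # speck dropped

    def test_intensity_scale_invariance(self, rest_frame):
        m1 = binarize_frame(rest_frame.astype(float))
        m2 = binarize_frame(rest_frame.astype(float) * 3.0)
        np.testing.assert_array_equal(m1, m2)


class TestOutline:
    def test_single_pixel_mask_has_minimal_closed_contour(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        outline = extract_outline(mask)
        assert len(outline) >= 4
        np.testing.assert_allclose(outline[0], outline[-1])

    def test_rectangle_perimeter(self):
        mask = np.zeros((40, 60), bool)
        mask[10:30, 10:50] = True  # 20 x 40
        outline = extract_outline(mask)
        perim = np.hypot(*np.diff(outline, axis=0).T).sum()
        assert perim == pytest.approx(2 * (20 + 40), rel=0.01)

    def test_circle_perimeter_after_smoothing(self):
        # the raw marching-squares contour of a binary disk carries the
        # classic ~5% staircase length bias; the pipeline's Savitzky-Golay
        # smoothing removes it, leaving the analytic perimeter within 1%
        mask = np.zeros((128, 128), bool)
        rr, cc = disk((64, 64), 50)
        mask[rr, cc] = True
        outline = smooth_outline(extract_outline(mask))
        perim = np.hypot(*np.diff(outline, axis=0).T).sum()
        assert perim == pytest.approx(2 * np.pi * 50, rel=0.01)

    def test_border_touching_mask_warns_and_clips(self):
        mask = np.zeros((10, 10), bool)
        mask[0:5, 0:5] = True
        with pytest.warns(UserWarning, match="border"):
            outline = extract_outline(mask)
        assert outline[:, 0].min() >= 0 and outline[:, 1].min() >= 0


class TestSmoothOutline:
    def test_quadratic_coordinates_reproduced_away_from_seam(self):
        # closed ring whose x/y are quadratic in index with matching endpoints;
        # an order-2 filter must reproduce them exactly except near the wrap
        n, w = 301, 75
        i = np.arange(n, dtype=float)
        ring = np.column_stack([(i - 150.0) ** 2, i * (n - 1 - i)])
        closed = np.vstack([ring, ring[0]])
        sm = smooth_outline(closed, SegmentationParams(sg_window=w))
        interior = slice(w // 2 + 1, n - w // 2 - 1)
        np.testing.assert_allclose(sm[interior], closed[interior], atol=1e-8)

    def test_circle_radial_deviation_below_half_pixel(self):
        theta = np.linspace(0, 2 * np.pi, 401)
        circle = np.column_stack([100 * np.cos(theta), 100 * np.sin(theta)])
        sm = smooth_outline(circle)
        r = np.hypot(sm[:, 0], sm[:, 1])
        assert np.abs(r - 100).max() < 0.5

    def test_short_outline_window_fallback(self):
        theta = np.linspace(0, 2 * np.pi, 42)
        circle = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta)])
        with pytest.warns(UserWarning, match="window"):
            sm = smooth_outline(circle, SegmentationParams(sg_window=75))
        assert len(sm) == len(circle)
        np.testing.assert_allclose(sm[0], sm[-1])


class TestLongestAxis:
    def _ellipse_mask(self, rotation):
        mask = np.zeros((256, 256), bool)
        rr, cc = draw_ellipse(128, 128, 40, 100, shape=mask.shape, rotation=rotation)
        mask[rr, cc] = True
        return mask

    def test_horizontal_ellipse(self):
        line = longest_axis(self._ellipse_mask(0.0))
        ang = np.degrees(np.arctan2(line.direction[1], line.direction[0]))
        assert abs(ang) < 1.0

    def test_rotation_equivariance_30_degrees(self):
        line = longest_axis(self._ellipse_mask(np.deg2rad(30)))
        ang = abs(np.degrees(np.arctan2(line.direction[1], line.direction[0])))
        assert ang == pytest.approx(30.0, abs=1.0)

    def test_square_tie_break_flagged_toward_x(self):
        mask = np.zeros((40, 40), bool)
        mask[10:30, 10:30] = True
        line = longest_axis(mask)
        assert line.isotropic_tie
        assert line.direction == (1.0, 0.0)


class TestLengthUnderLine:
    def test_ellipse_major_chord(self):
        yy, xx = np.mgrid[0:256, 0:256]
        mask = ((xx - 127.5) / 100.0) ** 2 + ((yy - 127.5) / 40.0) ** 2 <= 1.0
        line = longest_axis(mask)
        assert length_under_line(mask, line) == pytest.approx(200, abs=1.0)

    def test_thin_bar(self):
        mask = np.zeros((10, 60), bool)
        mask[5, 5:55] = True
        line = longest_axis(mask)
        assert length_under_line(mask, line) == pytest.approx(50, abs=1.0)

    def test_line_missing_mask_raises(self):
        mask = np.zeros((20, 20), bool)
        mask[2:5, 2:5] = True
        line = AxisLine(anchor=(15.0, 15.0), direction=(0.0, 1.0))
        with pytest.raises(ValueError, match="intersect"):
            length_under_line(mask, line)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_line_clipping_oracle_on_small_masks(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(6, 14)
        b = rng.uniform(3, a - 1)
        mask = np.zeros((32, 32), bool)
        rr, cc = draw_ellipse(16, 16, b, a, shape=mask.shape, rotation=rng.uniform(0, np.pi))
        mask[rr, cc] = True
        line = longest_axis(mask)
        assert length_under_line(mask, line) == pytest.approx(
            _line_clip_chord(mask, line), abs=0.5
        )


class TestTrackLength:
    def test_non_contracting_movie_gives_constant_trace(self):
        spec = CellMovieSpec(
            image_size=(128, 128), duration=0.4, rest_long_axis=80,
            rest_short_axis=30, contraction_ratio=1.0, event_onsets=(0.1,),
        )
        stack, _ = make_cell_movie(spec)
        trace = track_length(stack)
        assert np.ptp(trace.length) == 0.0

    def test_min_max_ratio_matches_contraction_ratio(self, small_movie):
        stack, _ = small_movie
        trace = track_length(stack)
        assert trace.length.min() / trace.length.max() == pytest.approx(0.876, abs=0.01)

    def test_event_count_visible_as_local_minima(self, small_movie):
        stack, gt = small_movie
        trace = track_length(stack)
        rest = np.median(trace.length)
        below = trace.length < 0.95 * rest
        n_dips = np.sum(np.diff(below.astype(int)) == 1)
        assert n_dips == gt.truth["n_events"]

    def test_rotation_by_90_degrees_leaves_lengths_unchanged(self, small_movie):
        stack, _ = small_movie
        sub = ImageStack(stack.frames[:30], stack.frame_interval)
        rotated = ImageStack(np.rot90(sub.frames, axes=(1, 2)).copy(), sub.frame_interval)
        t1 = track_length(sub)
        t2 = track_length(rotated)
        np.testing.assert_allclose(t1.length, t2.length, atol=1.0)

    def test_intensity_scaling_leaves_lengths_unchanged(self, small_movie):
        stack, _ = small_movie
        sub = ImageStack(stack.frames[:20].astype(float), stack.frame_interval)
        scaled = ImageStack(sub.frames * 2.5, sub.frame_interval)
        np.testing.assert_allclose(
            track_length(sub).length, track_length(scaled).length, atol=1e-9
        )


class TestKymograph:
    def test_shape_and_static_rows(self):
        spec = CellMovieSpec(
            image_size=(96, 96), duration=0.4, rest_long_axis=60,
            rest_short_axis=24, contraction_ratio=1.0, event_onsets=(),
        )
        stack, _ = make_cell_movie(spec)
        line = longest_axis(binarize_frame(stack.frames[0]))
        kymo = make_kymograph(stack, line)
        assert kymo.shape[0] == stack.n_frames
        assert all((row == kymo[0]).all() for row in kymo)

    def test_band_width_oscillates_with_contraction(self, small_movie):
        stack, gt = small_movie
        line = longest_axis(binarize_frame(stack.frames[0]))
        kymo = make_kymograph(stack, line)
        thresh = (kymo.max() + kymo.min()) / 2.0
        widths = (kymo > thresh).sum(axis=1)
        trace = track_length(stack)
        # band width tracks the length trace
        r = np.corrcoef(widths, trace.length)[0, 1]
        assert r > 0.99
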