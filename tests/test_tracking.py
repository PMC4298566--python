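"""Segmentation, skeleton tracing, midpoint and angle computation."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from flagellabeat import (BeatProtocol, RenderParams, VideoStack, angle_series,
                          binarize, generate_video, locate_head, midpoint,
                          symmetry_axis, trace_flagellum)
from flagellabeat.synthetic_data import _curve_to_px, curve_mask
from flagellabeat.tracking import (FlagellumTrace, HeadPose,
                                   SegmentationError, TracingError,
                                   TrackingLostError)


class TestBinarize:
    def test_perfectly_separable_image(self):
        img = np.full((50, 50), 10, np.uint8)
        img[10:20, 10:30] = 200
        fg = binarize(img)
        assert np.array_equal(fg, img == 200)

    def test_uniform_image_raises(self):
        with pytest.raises(SegmentationError, match="zero-variance"):
            binarize(np.full((32, 32), 7, np.uint8))

    def test_noisy_frame_matches_generator_mask(self, short_video):
        video, truth = short_video
        rend = RenderParams(noise_sigma=9.0)
        fg = binarize(video.frames[0])
        mask = curve_mask(truth.curves_um[0],
                          (truth.frames.head_x_px[0], truth.frames.head_y_px[0]),
                          rend)
        assert (fg & mask).sum() / (fg | mask).sum() >= 0.8

    def test_keeps_largest_component_only(self):
        img = np.full((60, 60), 10, np.uint8)
        img[5:8, 5:8] = 200          # small distractor
        img[20:40, 20:45] = 200      # the cell
        fg = binarize(img)
        assert not fg[6, 6] and fg[30, 30]


class TestLocateHead:
    def test_disk_centroid_recovered(self):
        img = np.zeros((100, 100), bool)
        yy, xx = np.mgrid[0:100, 0:100]
        img[np.hypot(xx - 50, yy - 60) <= 8] = True
        pose = locate_head(img)
        assert np.hypot(pose.center[0] - 50, pose.center[1] - 60) <= 0.5

    def test_tracks_drifting_head_within_one_px(self, beat_video_cache):
        video, truth = beat_video_cache(duration_s=0.2,
                                        drift_px_per_frame=(0.2, -0.1))
        prior = None
        for k in range(len(video)):
            fg = binarize(video.frames[k])
            pose = locate_head(fg, prior=prior, intensity=video.frames[k],
                               frame_index=k)
            prior = pose.center
            err = np.hypot(pose.center[0] - truth.frames.head_x_px[k],
                           pose.center[1] - truth.frames.head_y_px[k])
            assert err <= 1.0

    def test_empty_foreground_raises(self):
        with pytest.raises(TrackingLostError):
            locate_head(np.zeros((20, 20), bool))

    def test_prior_window_excluding_cell_raises(self):
        img = np.zeros((100, 100), bool)
        img[40:60, 40:60] = True
        with pytest.raises(TrackingLostError, match="prior"):
            locate_head(img, prior=(5.0, 5.0), search_radius_px=10)


class TestTraceFlagellum:
    def test_straight_bar_ordered_head_first(self):
        bar = np.zeros((20, 100), bool)
        bar[8:11, 5:95] = True
        trace = trace_flagellum(bar, HeadPose(0, (5.0, 9.0)))
        assert trace.points[0, 0] < trace.points[-1, 0]
        assert np.all(np.diff(trace.points[:, 0]) >= 0)
        extent = 94 - 5  # head-end pixel to tip pixel
        assert abs(trace.arc_length_px - extent) <= 1.0

    def test_reversed_head_reverses_order(self):
        bar = np.zeros((20, 100), bool)
        bar[8:11, 5:95] = True
        trace = trace_flagellum(bar, HeadPose(0, (94.0, 9.0)))
        assert trace.points[0, 0] > trace.points[-1, 0]

    def test_consecutive_points_8_connected(self, short_video):
        video, _ = short_video
        fg = binarize(video.frames[0])
        pose = locate_head(fg, intensity=video.frames[0])
        trace = trace_flagellum(fg, pose)
        steps = np.abs(np.diff(trace.points, axis=0))
        assert np.all(steps <= 1)

    def test_rendered_curve_traced_accurately(self, short_video):
        """Mean distance to the true curve <= 1 px; arc within 5% of L."""
        video, truth = short_video
        L_px = 60.0 / video.um_per_px
        for k in [0, 10, 20]:
            fg = binarize(video.frames[k])
            pose = locate_head(fg, intensity=video.frames[k], frame_index=k)
            trace = trace_flagellum(fg, pose)
            true_px = _curve_to_px(
                truth.curves_um[k],
                (truth.frames.head_x_px[k], truth.frames.head_y_px[k]),
                video.um_per_px)
            d, _ = cKDTree(true_px).query(trace.points)
            assert d.mean() <= 1.0
            assert abs(trace.arc_length_px - L_px) / L_px <= 0.05

    def test_ring_foreground_raises_loop_error(self):
        yy, xx = np.mgrid[0:60, 0:60]
        r = np.hypot(xx - 30, yy - 30)
        ring = (r > 10) & (r < 14)
        with pytest.raises(TracingError, match="loop"):
            trace_flagellum(ring, HeadPose(0, (30.0, 20.0)))


class TestMidpoint:
    def test_straight_trace(self):
        pts = np.column_stack([np.arange(101.0), np.zeros(101)])
        trace = FlagellumTrace(0, pts, 100.0)
        assert midpoint(trace) == (50.0, 0.0)

    def test_right_angle_arc_length_interpolation(self):
        # (0,0)->(0,30)->(40,30): half of 70 is 35, i.e. 5 px past the corner
        pts = np.vstack([np.column_stack([np.zeros(31), np.arange(31.0)]),
                         np.column_stack([np.arange(1.0, 41), np.full(40, 30.0)])])
        seg = np.diff(pts, axis=0)
        trace = FlagellumTrace(0, pts, float(np.hypot(*seg.T).sum()))
        assert np.allclose(midpoint(trace), (5.0, 30.0))

    def test_two_point_trace(self):
        trace = FlagellumTrace(0, np.array([[0.0, 0.0], [10.0, 0.0]]), 10.0)
        assert midpoint(trace) == (5.0, 0.0)


class TestSymmetryAxis:
    def test_single_direction(self):
        assert symmetry_axis([0.7]) == pytest.approx(0.7)

    def test_symmetric_pair_averages_to_zero(self):
        assert symmetry_axis([0.3, -0.3]) == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_directions_raise(self):
        with pytest.raises(ValueError, match="resultant"):
            symmetry_axis([0.0, np.pi])

    def test_recovers_generator_base_orientation(self, beat_video_cache):
        video, truth = beat_video_cache(duration_s=0.4,
                                        base_orientation_rad=0.3)
        series = angle_series(video, window_s=0.1)
        axis = series.axis_rad[np.isfinite(series.axis_rad)]
        assert np.abs(np.degrees(axis - 0.3)).max() <= 1.0


class TestAngleSeries:
    def test_matches_ground_truth_angles(self, beat_video_cache):
        video, truth = beat_video_cache(duration_s=1.2)
        series = angle_series(video)
        truth_ang = truth.frames.midpoint_angle_rad.to_numpy()
        ok = np.isfinite(series.angles)
        assert ok.mean() >= 0.9
        assert np.abs(series.angles[ok] - truth_ang[ok]).max() <= 0.05

    def test_rotation_equivariance(self, beat_video_cache):
        """Rotating frames 90 deg rotates the axis and keeps angles."""
        video, _ = beat_video_cache(duration_s=0.3, base_orientation_rad=0.2)
        rotated = VideoStack(
            frames=np.stack([np.rot90(f) for f in video.frames]),
            fps=video.fps, um_per_px=video.um_per_px)
        a0 = angle_series(video, window_s=0.1)
        a1 = angle_series(rotated, window_s=0.1)
        ok = np.isfinite(a0.angles) & np.isfinite(a1.angles)
        assert np.abs(a1.angles[ok] - a0.angles[ok]).max() <= 0.02
        d_axis = (a1.axis_rad[ok] - a0.axis_rad[ok]) % (2 * np.pi)
        assert np.allclose(d_axis, np.pi / 2, atol=0.02)

    def test_scale_consistency_at_double_resolution(self):
        """arc_length_px * um_per_px invariant to 2x rendering within 2%."""
        lengths = []
        for scale in (1.0, 2.0):
            prot = BeatProtocol(duration_s=0.01,
                                head_center_px=(90.0 * scale, 128.0 * scale))
            rend = RenderParams(
                image_size_px=(int(256 * scale), int(256 * scale)),
                um_per_px=0.6875 / scale, noise_sigma=0.0)
            video, _ = generate_video(prot, rend)
            fg = binarize(video.frames[0])
            pose = locate_head(fg, intensity=video.frames[0])
            trace = trace_flagellum(fg, pose)
            lengths.append(trace.arc_length_px * rend.um_per_px)
        assert abs(lengths[1] - lengths[0]) / lengths[0] <= 0.02
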