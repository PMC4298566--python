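"""Head registration, neck azimuth and envelope superposition."""

import numpy as np
import pytest

from flagellabeat import (Annulus, BeatProtocol, RenderParams, VideoStack,
                          align_and_superimpose, binarize, generate_video,
                          locate_head, neck_azimuth, register_head)
from flagellabeat.tracking import HeadPose, TrackingLostError
from flagellabeat.waveform_alignment import NeckAzimuthError, _align_one


def measure_poses_azimuths(video):
    heads, azimuths = [], []
    for k in range(len(video)):
        fg = binarize(video.frames[k])
        pose = locate_head(fg, intensity=video.frames[k], frame_index=k)
        heads.append(pose)
        azimuths.append(neck_azimuth(fg, pose, Annulus(center=pose.center),
                                     video.um_per_px))
    return heads, azimuths


class TestAnnulus:
    def test_default_dimensions_cover_head_plus_4um(self):
        ann = Annulus(center=(128.0, 128.0))
        assert ann.inner_diameter_um == 16.0
        assert ann.outer_diameter_um == 20.0

    def test_annulus_outside_image_raises(self):
        ann = Annulus(center=(2.0, 2.0))
        with pytest.raises(ValueError, match="fit"):
            ann.mask((256, 256), 0.6875)


class TestRegisterHead:
    def test_static_video_constant_center(self, beat_video_cache):
        video, truth = beat_video_cache(duration_s=0.2)
        heads = register_head(video, (90.0, 128.0, 12.0))
        errs = [np.hypot(h.center[0] - truth.frames.head_x_px[k],
                         h.center[1] - truth.frames.head_y_px[k])
                for k, h in enumerate(heads)]
        assert max(errs) <= 0.5

    def test_known_drift_recovered(self, beat_video_cache):
        video, truth = beat_video_cache(duration_s=0.2,
                                        drift_px_per_frame=(0.2, -0.1))
        heads = register_head(video, (90.0, 128.0, 12.0))
        errs = np.array([np.hypot(h.center[0] - truth.frames.head_x_px[k],
                                  h.center[1] - truth.frames.head_y_px[k])
                         for k, h in enumerate(heads)])
        assert np.sqrt(np.mean(errs ** 2)) <= 0.5

    def test_roi_without_head_raises_at_frame_zero(self, beat_video_cache):
        video, _ = beat_video_cache(duration_s=0.05)
        with pytest.raises(TrackingLostError, match="frame 0"):
            register_head(video, (220.0, 30.0, 10.0))


class TestNeckAzimuth:
    def test_flagellum_along_plus_x_gives_zero(self):
        img = np.zeros((256, 256), bool)
        yy, xx = np.mgrid[0:256, 0:256]
        img[np.hypot(xx - 128, yy - 128) <= 10] = True
        img[126:131, 128:200] = True
        az = neck_azimuth(img, HeadPose(0, (128.0, 128.0)),
                          Annulus(center=(128.0, 128.0)), 0.6875)
        assert abs(az) <= 0.05

    def test_matches_base_orientation_at_phase_zero(self, beat_video_cache):
        video, truth = beat_video_cache(duration_s=0.05,
                                        base_orientation_rad=0.4,
                                        amplitude_rad=0.05)
        fg = binarize(video.frames[0])
        pose = locate_head(fg, intensity=video.frames[0])
        az = neck_azimuth(fg, pose, Annulus(center=pose.center),
                          video.um_per_px)
        assert abs(np.degrees(az - 0.4)) <= 2.0

    def test_empty_annulus_raises(self):
        img = np.zeros((256, 256), bool)
        img[120:137, 120:137] = True  # head only, no neck
        with pytest.raises(NeckAzimuthError, match="annulus"):
            neck_azimuth(img, HeadPose(0, (200.0, 128.0)),
                         Annulus(center=(200.0, 128.0)), 0.6875)

    def test_opposite_sectors_ambiguous(self):
        img = np.zeros((256, 256), bool)
        img[126:131, 60:200] = True  # straight line through the head
        with pytest.raises(NeckAzimuthError, match="ambiguous"):
            neck_azimuth(img, HeadPose(0, (128.0, 128.0)),
                         Annulus(center=(128.0, 128.0)), 0.6875)


class TestAlignAndSuperimpose:
    def test_identical_frames_idempotent(self, beat_video_cache):
        video, _ = beat_video_cache(duration_s=0.05)
        frame = video.frames[0]
        stack = VideoStack(np.stack([frame] * 5), 200.0, video.um_per_px)
        heads = [HeadPose(k, (90.0, 128.0)) for k in range(5)]
        env = align_and_superimpose(stack, heads, [0.1] * 5)
        assert env.n_frames_used == 5
        # identical pose and azimuth: envelope equals one aligned frame
        single = align_and_superimpose(
            VideoStack(frame[None], 200.0, video.um_per_px),
            heads[:1], [0.1])
        assert np.allclose(env.image, single.image, atol=1e-9)

    def test_single_frame_translated_and_rotated_only(self, beat_video_cache):
        video, _ = beat_video_cache(duration_s=0.05)
        stack = VideoStack(video.frames[:1], 200.0, video.um_per_px)
        env = align_and_superimpose(stack, [HeadPose(0, (90.0, 128.0))], [0.3])
        # reference frame: rotation is identity, so pixels are preserved
        assert np.allclose(env.image, video.frames[0].astype(float),
                           atol=1e-6)

    def test_double_alignment_is_identity(self, beat_video_cache):
        video, _ = beat_video_cache(duration_s=0.05, noise_sigma=0.0)
        frame = video.frames[0].astype(float)
        once = _align_one(frame, (90.0, 128.0), (128.0, 128.0), 0.4)
        back = _align_one(once, (128.0, 128.0), (90.0, 128.0), -0.4)
        core = (slice(40, 216), slice(40, 216))
        diff = np.abs(back[core] - frame[core])
        assert diff.mean() <= 1.0          # interpolation tolerance
        assert np.quantile(diff, 0.99) <= 15.0

    def test_rigid_rotation_self_consistency(self, beat_video_cache):
        """Azimuths recomputed on aligned frames are constant within 2 deg."""
        video, _ = beat_video_cache(duration_s=0.15, amplitude_rad=0.0,
                                    rotation_rad_per_frame=0.02,
                                    head_center_px=(128.0, 128.0),
                                    noise_sigma=0.0)
        heads, azimuths = measure_poses_azimuths(video)
        env = align_and_superimpose(video, heads, azimuths)
        realigned = []
        recentered = []
        for k in range(len(video)):
            aligned = _align_one(video.frames[k], heads[k].center,
                                 env.reference_center,
                                 env.reference_azimuth - azimuths[k])
            fg = binarize(aligned.astype(np.uint8), frame_index=k)
            pose = locate_head(fg, intensity=aligned, frame_index=k)
            recentered.append(np.hypot(pose.center[0] - env.reference_center[0],
                                       pose.center[1] - env.reference_center[1]))
            realigned.append(neck_azimuth(fg, pose,
                                          Annulus(center=pose.center),
                                          video.um_per_px))
        assert max(recentered) <= 1.0
        assert np.degrees(np.ptp(realigned)) <= 2.0

    def test_one_beat_period_covers_envelope(self, beat_video_cache):
        """One period of a constant-f beat sweeps >= 95% of five periods."""
        video, _ = beat_video_cache(f_hz=10.0, duration_s=0.55,
                                    noise_sigma=0.0)
        period = int(round(video.fps / 10.0))
        heads, azimuths = measure_poses_azimuths(video)
        env1 = align_and_superimpose(
            VideoStack(video.frames[:period], video.fps, video.um_per_px),
            heads[:period], azimuths[:period])
        env5 = align_and_superimpose(
            VideoStack(video.frames[:5 * period], video.fps, video.um_per_px),
            heads[:5 * period], azimuths[:5 * period])
        thr = 30.0
        m1, m5 = env1.image > thr, env5.image > thr
        assert (m1 & m5).sum() / m5.sum() >= 0.95

    def test_all_gapped_frames_raise(self, beat_video_cache):
        video, _ = beat_video_cache(duration_s=0.05)
        stack = VideoStack(video.frames[:3], 200.0, video.um_per_px)
        with pytest.raises(ValueError, match="gapped"):
            align_and_superimpose(stack, [None] * 3, [None] * 3)
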