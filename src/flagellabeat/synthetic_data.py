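"""Synthetic dark-field recordings of a tethered sperm with known ground truth.

A head-tethered sperm is modelled as a rigid head disk plus a flagellum whose
tangent angle follows a travelling wave

    psi(s, t) = theta0 + A * sin(phi(t) - 2*pi*s/lambda),

where ``s`` is arc length from the head attachment point, ``theta0`` the
orientation of the cell's symmetry axis, ``A`` the tangent-angle amplitude and
``phi(t) = 2*pi * integral of f(tau) dtau`` the beat phase accumulated from a
programmable instantaneous-frequency time course ``f(t)``.  Frames are
rendered as a bright Gaussian-profile ridge on a dark background, emulating
dark-field contrast, and every frame carries an exact ground-truth record so
downstream tracking and frequency estimation can be validated without any
real microscopy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage


__all__ = [
    "FrequencyProfile",
    "BeatProtocol",
    "RenderParams",
    "GroundTruth",
    "TraceProtocol",
    "FluorescenceTrace",
    "flagellum_curve",
    "render_frame",
    "curve_mask",
    "generate_video",
    "generate_trace",
]


class FrequencyProfile:
    """Instantaneous beat frequency f(t) in Hz with an exact phase integral.

    ``phase(t)`` returns ``2*pi * integral_0^t f(tau) dtau``; for the built-in
    constant and step profiles the integral is analytic, for arbitrary
    callables it is accumulated numerically on a fine grid.
    """

    def __init__(self, frequency: Callable[[float], float],
                 phase: Callable[[float], float] | None = None,
                 dt: float = 1e-4):
        self._frequency = frequency
        if phase is None:
            def phase(t: float, _f=frequency, _dt=dt) -> float:
                if t <= 0:
                    return 0.0
                n = max(int(np.ceil(t / _dt)), 2)
                grid = np.linspace(0.0, t, n + 1)
                vals = np.array([_f(float(g)) for g in grid])
                return float(2.0 * np.pi * np.trapezoid(vals, grid))
        self._phase = phase

    def frequency(self, t):
        if np.ndim(t) == 0:
            return float(self._frequency(float(t)))
        return np.array([self._frequency(float(x)) for x in np.asarray(t)])

    def phase(self, t):
        if np.ndim(t) == 0:
            return float(self._phase(float(t)))
        return np.array([self._phase(float(x)) for x in np.asarray(t)])

    @staticmethod
    def constant(f_hz: float) -> "FrequencyProfile":
        return FrequencyProfile(lambda t: f_hz, lambda t: 2.0 * np.pi * f_hz * t)

    @staticmethod
    def step(f_before: float, f_after: float, t_step: float) -> "FrequencyProfile":
        """Abrupt frequency change at ``t_step`` (e.g. a light flash)."""
        def freq(t: float) -> float:
            return f_before if t < t_step else f_after

        def phase(t: float) -> float:
            if t <= t_step:
                return 2.0 * np.pi * f_before * t
            return 2.0 * np.pi * (f_before * t_step + f_after * (t - t_step))

        return FrequencyProfile(freq, phase)


@dataclass
class BeatProtocol:
    """Kinematic programme of the synthetic cell.

    The head is tethered: its centre moves only through the explicit
    ``drift_px_per_frame`` and the whole cell reorients only through
    ``rotation_rad_per_frame``.
    """

    duration_s: float = 2.0
    fps: float = 200.0
    frequency_fn: FrequencyProfile = field(
        default_factory=lambda: FrequencyProfile.constant(10.0))
    event_time_s: float | None = None
    amplitude_rad: float = 0.35
    wavelength_um: float = 120.0
    flagellum_length_um: float = 60.0
    base_orientation_rad: float = 0.0
    head_center_px: tuple[float, float] = (90.0, 128.0)
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)
    rotation_rad_per_frame: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.flagellum_length_um <= 0:
            raise ValueError("flagellum_length_um must be positive")
        if self.amplitude_rad < 0:
            raise ValueError("amplitude_rad must be non-negative")
        times = np.arange(self.n_frames) / self.fps
        freqs = self.frequency_fn.frequency(times)
        if np.any(np.asarray(freqs) < 0):
            raise ValueError("frequency_fn must be non-negative over the video")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def event_frame(self) -> int | None:
        if self.event_time_s is None:
            return None
        return int(round(self.event_time_s * self.fps))


@dataclass
class RenderParams:
    """Appearance of the rendered dark-field frame (bright cell, dark field)."""

    image_size_px: tuple[int, int] = (256, 256)  # (width, height)
    um_per_px: float = 11.0 / 16.0  # 11 um camera pixel at 16x magnification
    background_level: float = 10.0
    flagellum_peak: float = 180.0
    line_sigma_px: float = 1.2
    head_radius_um: float = 4.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.flagellum_peak <= self.background_level:
            raise ValueError("flagellum_peak must exceed background_level")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class GroundTruth:
    """Exact per-frame truth emitted alongside the rendered video."""

    frames: pd.DataFrame  # frame, time_s, head_x_px, head_y_px, neck_azimuth_rad,
    #                       midpoint_angle_rad, frequency_hz
    curves_um: list[np.ndarray]  # per frame (n_pts, 2) y-up um coords, head-relative
    event_frame: int | None = None

    def to_csv(self, path) -> None:
        self.frames.to_csv(path, index=False)


@dataclass
class TraceProtocol:
    """Programme for a synthetic fluorescence trace: baseline, then a response."""

    n_samples: int = 200
    sample_interval_s: float = 0.5
    baseline_level: float = 100.0
    response_shape: str = "none"  # none | step | saturating_exponential
    response_amplitude: float = 0.0
    response_tau_s: float = 5.0
    event_index: int | None = 40
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.baseline_level <= 0:
            raise ValueError("baseline_level must be positive")
        if self.response_shape not in ("none", "step", "saturating_exponential"):
            raise ValueError(f"unknown response_shape {self.response_shape!r}")
        if self.response_shape != "none":
            if self.event_index is None or not (0 < self.event_index < self.n_samples):
                raise ValueError("event_index must lie strictly inside the trace")


@dataclass
class FluorescenceTrace:
    """Time-stamped intensity samples with the index of compound addition."""

    times: np.ndarray
    values: np.ndarray
    event_index: int | None
    instrument: str = "plate_reader"  # plate_reader | stopped_flow

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


# ---------------------------------------------------------------------------
# flagellum geometry

def flagellum_curve(protocol: BeatProtocol, t: float,
                    ds_um: float = 0.25) -> np.ndarray:
    """Flagellum centreline at time ``t`` as (n, 2) y-up um coordinates.

    The curve starts at the head attachment point (origin) and is built by
    stepping along the tangent-angle wave with fixed-length chords, so the
    polyline arc length equals ``flagellum_length_um`` exactly.
    """
    if not (0.0 <= t <= protocol.duration_s):
        raise ValueError(
            f"t={t} outside the recording interval [0, {protocol.duration_s}]")
    L = protocol.flagellum_length_um
    n_seg = max(int(np.ceil(L / min(ds_um, 0.5))), 2)
    ds = L / n_seg
    s_mid = (np.arange(n_seg) + 0.5) * ds
    phi = protocol.frequency_fn.phase(t)
    frame_idx = t * protocol.fps
    theta0 = protocol.base_orientation_rad + protocol.rotation_rad_per_frame * frame_idx
    psi = theta0 + protocol.amplitude_rad * np.sin(
        phi - 2.0 * np.pi * s_mid / protocol.wavelength_um)
    steps = ds * np.column_stack([np.cos(psi), np.sin(psi)])
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return pts


def _curve_to_px(curve_um: np.ndarray, head_center_px: Sequence[float],
                 um_per_px: float) -> np.ndarray:
    """Map head-relative y-up um coordinates to storage (x right, y down) px."""
    x = head_center_px[0] + curve_um[:, 0] / um_per_px
    y = head_center_px[1] - curve_um[:, 1] / um_per_px
    return np.column_stack([x, y])


def _distance_to_polyline(shape_hw: tuple[int, int],
                          pts_px: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance to a densely sampled polyline."""
    h, w = shape_hw
    # densify so consecutive samples are < 0.35 px apart, then use an EDT
    seg = np.diff(pts_px, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    dense = [pts_px[:1]]
    for i, sl in enumerate(seglen):
        n = max(int(np.ceil(sl / 0.35)), 1)
        frac = np.arange(1, n + 1)[:, None] / n
        dense.append(pts_px[i] + frac * seg[i])
    dpts = np.vstack(dense)
    mask = np.ones((h, w), dtype=bool)
    cols = np.clip(np.round(dpts[:, 0]).astype(int), 0, w - 1)
    rows = np.clip(np.round(dpts[:, 1]).astype(int), 0, h - 1)
    mask[rows, cols] = False
    return ndimage.distance_transform_edt(mask)


def render_frame(curve_um: np.ndarray, head_center_px: Sequence[float],
                 render: RenderParams,
                 rng: np.random.Generator | None = None,
                 frame_index: int | None = None) -> np.ndarray:
    """Render one grayscale frame: Gaussian-ridge flagellum plus a head disk.

    Intensity = background + peak * exp(-d^2 / 2 sigma^2) along the flagellum,
    with a filled disk of ``head_radius_um`` at the head centre, additive
    Gaussian noise, clipped to [0, 255] and quantized to uint8.
    """
    if len(curve_um) == 0:
        raise ValueError("curve must be non-empty")
    w, h = render.image_size_px
    pts = _curve_to_px(np.asarray(curve_um, float), head_center_px, render.um_per_px)
    margin = 2.0 * render.line_sigma_px
    if (pts[:, 0].min() < -margin or pts[:, 0].max() > w - 1 + margin
            or pts[:, 1].min() < -margin or pts[:, 1].max() > h - 1 + margin):
        where = f" in frame {frame_index}" if frame_index is not None else ""
        raise ValueError(f"flagellum leaves the field of view{where}")
    d = _distance_to_polyline((h, w), pts)
    img = render.background_level + render.flagellum_peak * np.exp(
        -0.5 * (d / render.line_sigma_px) ** 2)
    # head disk with a soft Gaussian rim so the centroid stays unbiased
    yy, xx = np.mgrid[0:h, 0:w]
    r_head = render.head_radius_um / render.um_per_px
    dhead = np.hypot(xx - head_center_px[0], yy - head_center_px[1])
    head = np.where(dhead <= r_head, 1.0,
                    np.exp(-0.5 * ((dhead - r_head) / render.line_sigma_px) ** 2))
    img = np.maximum(img, render.background_level + render.flagellum_peak * head)
    if render.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(render.seed)
        img = img + rng.normal(0.0, render.noise_sigma, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def curve_mask(curve_um: np.ndarray, head_center_px: Sequence[float],
               render: RenderParams) -> np.ndarray:
    """Ground-truth foreground mask: pixels within 2*line_sigma of the
    rendered structure (the flagellum centreline or the head-disk boundary)."""
    w, h = render.image_size_px
    pts = _curve_to_px(np.asarray(curve_um, float), head_center_px, render.um_per_px)
    d = _distance_to_polyline((h, w), pts)
    yy, xx = np.mgrid[0:h, 0:w]
    r_head = render.head_radius_um / render.um_per_px
    dhead = np.hypot(xx - head_center_px[0], yy - head_center_px[1])
    reach = 2.0 * render.line_sigma_px
    return (d <= reach) | (dhead <= r_head + reach)


def _signed_angle(v: np.ndarray) -> float:
    return float(np.arctan2(v[1], v[0]))


def _wrap(a):
    """Wrap angle(s) to (-pi, pi]."""
    return -((-np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi)


def _midpoint_um(curve_um: np.ndarray) -> np.ndarray:
    seg = np.diff(curve_um, axis=0)
    slen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(slen)])
    half = cum[-1] / 2.0
    i = int(np.searchsorted(cum, half)) - 1
    i = min(max(i, 0), len(slen) - 1)
    frac = (half - cum[i]) / slen[i]
    return curve_um[i] + frac * seg[i]


def _radius_crossing_um(curve_um: np.ndarray, radius_um: float) -> np.ndarray:
    """First point where the curve crosses a circle of ``radius_um`` about the
    head attachment point (linear interpolation between samples)."""
    r = np.hypot(curve_um[:, 0], curve_um[:, 1])
    idx = np.nonzero(r >= radius_um)[0]
    if len(idx) == 0:
        return curve_um[-1]
    j = idx[0]
    if j == 0:
        return curve_um[0]
    f = (radius_um - r[j - 1]) / (r[j] - r[j - 1])
    return curve_um[j - 1] + f * (curve_um[j] - curve_um[j - 1])


def generate_video(protocol: BeatProtocol, render: RenderParams):
    """Render the full recording; returns ``(VideoStack, GroundTruth)``.

    Geometry is validated for every frame before the first frame is rendered,
    so an inconsistent protocol/render combination fails fast.
    """
    from .tracking import VideoStack  # local import avoids a cycle at import time

    n = protocol.n_frames
    times = np.arange(n) / protocol.fps
    heads = np.array(protocol.head_center_px, float) + np.outer(
        np.arange(n), protocol.drift_px_per_frame)
    curves = [flagellum_curve(protocol, float(t)) for t in times]

    w, h = render.image_size_px
    margin = 2.0 * render.line_sigma_px
    for k, (curve, head) in enumerate(zip(curves, heads)):
        pts = _curve_to_px(curve, head, render.um_per_px)
        if (pts[:, 0].min() < -margin or pts[:, 0].max() > w - 1 + margin
                or pts[:, 1].min() < -margin or pts[:, 1].max() > h - 1 + margin):
            raise ValueError(
                f"protocol/render geometry inconsistent: cell leaves the "
                f"field of view at frame {k}")

    rng = np.random.default_rng(render.seed)
    frames = np.empty((n, h, w), dtype=np.uint8)
    for k, (curve, head) in enumerate(zip(curves, heads)):
        frames[k] = render_frame(curve, head, render, rng=rng, frame_index=k)

    neck_radius = 9.0  # um, mid annulus ring (16/20 um diameters)
    records = []
    for k, (t, curve, head) in enumerate(zip(times, curves, heads)):
        theta0 = (protocol.base_orientation_rad
                  + protocol.rotation_rad_per_frame * k)
        mid = _midpoint_um(curve)
        neck = _radius_crossing_um(curve, neck_radius)
        records.append({
            "frame": k,
            "time_s": float(t),
            "head_x_px": float(head[0]),
            "head_y_px": float(head[1]),
            "neck_azimuth_rad": _signed_angle(neck),
            "midpoint_angle_rad": float(_wrap(_signed_angle(mid) - theta0)),
            "axis_rad": float(theta0),
            "frequency_hz": float(protocol.frequency_fn.frequency(float(t))),
        })
    truth = GroundTruth(frames=pd.DataFrame.from_records(records),
                        curves_um=curves, event_frame=protocol.event_frame)
    events = [] if protocol.event_frame is None else [protocol.event_frame]
    stack = VideoStack(frames=frames, fps=protocol.fps,
                       um_per_px=render.um_per_px, event_frames=events)
    return stack, truth


def generate_trace(protocol: TraceProtocol) -> FluorescenceTrace:
    """Synthesize a fluorescence trace: baseline, then the programmed response."""
    t = np.arange(protocol.n_samples) * protocol.sample_interval_s
    values = np.full(protocol.n_samples, protocol.baseline_level, dtype=float)
    ev = protocol.event_index
    if protocol.response_shape == "step":
        values[ev:] += protocol.response_amplitude
    elif protocol.response_shape == "saturating_exponential":
        dt = t[ev:] - t[ev]
        values[ev:] += protocol.response_amplitude * (
            1.0 - np.exp(-dt / protocol.response_tau_s))
    if protocol.noise_sigma > 0:
        rng = np.random.default_rng(protocol.seed)
        values = values + rng.normal(0.0, protocol.noise_sigma, values.shape)
    return FluorescenceTrace(times=t, values=values, event_index=ev,
                             instrument="plate_reader")
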