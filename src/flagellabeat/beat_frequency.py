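"""Per-frame beat-frequency estimation by sliding-window sinusoid fitting.

The head-midflagellum angle of a beating cell oscillates sinusoidally; the
beat frequency is obtained by least-squares fitting

    a * sin(2*pi*f*t + phi) + c

to the angle samples inside each frame's window (0.5 s before and after the
frame, shifted but never shrunk at video boundaries or around a light flash;
see :mod:`flagellabeat.windows`).  The fit is initialized deterministically
from the zero-padded discrete-Fourier peak of the detrended samples, with the
frequency search bounded away from DC drift and aliasing artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .tracking import AngleSeries
from .windows import WindowError, window_bounds, window_size

__all__ = [
    "SinusoidFit", "BeatFrequencySeries",
    "fit_sinusoid", "fft_peak_frequency", "frequency_series",
    "window_bounds", "window_size", "moving_average",
]


@dataclass
class SinusoidFit:
    frequency: float      # Hz; NaN when not converged
    amplitude: float      # radians, non-negative
    phase: float          # radians in (-pi, pi]
    offset: float
    rss: float
    r_squared: float
    converged: bool


@dataclass
class BeatFrequencySeries:
    """Per-frame frequency estimates with window bookkeeping and diagnostics."""

    frame: np.ndarray
    time_s: np.ndarray
    frequency_hz: np.ndarray      # NaN marks a gap
    amplitude_rad: np.ndarray
    r_squared: np.ndarray
    window_start: np.ndarray
    window_end: np.ndarray
    status: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": self.frame, "time_s": self.time_s,
            "frequency_hz": self.frequency_hz,
            "amplitude_rad": self.amplitude_rad,
            "r_squared": self.r_squared,
            "window_start": self.window_start,
            "window_end": self.window_end,
            "status": self.status,
        })


def _wrap(a):
    return -((-np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi)


def fft_peak_frequency(t: np.ndarray, y: np.ndarray, pad_factor: int = 8,
                       f_bounds: tuple[float, float] | None = None) -> float:
    """Frequency of the zero-padded FFT peak of a detrended, uniformly
    sampled series.  Used both as fit initialization and as an independent
    cross-check of the least-squares estimate."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    dt = float(np.median(np.diff(t)))
    yd = y - y.mean()
    n = len(y) * pad_factor
    spec = np.abs(np.fft.rfft(yd, n=n))
    freqs = np.fft.rfftfreq(n, d=dt)
    if f_bounds is not None:
        ok = (freqs >= f_bounds[0]) & (freqs <= f_bounds[1])
        if not ok.any():
            return float("nan")
        freqs, spec = freqs[ok], spec[ok]
    else:
        freqs, spec = freqs[1:], spec[1:]  # drop DC
    return float(freqs[int(np.argmax(spec))])


def fit_sinusoid(times, angles, f_init: float | None = None,
                 f_bounds: tuple[float, float] | None = None,
                 noise_floor_factor: float = 1.0) -> SinusoidFit:
    """Least-squares fit of ``a*sin(2*pi*f*t + phi) + c`` to angle samples.

    Parameters
    ----------
    f_init:
        Starting frequency; when absent it is taken from the discrete-Fourier
        peak of the detrended samples.
    f_bounds:
        Allowed frequency range; defaults to [0.5, 1/(4*dt)] Hz, excluding DC
        drift and frequencies too close to the sampling rate.
    noise_floor_factor:
        A converged fit whose amplitude falls below this multiple of the
        residual RMS is flagged failed (no detectable oscillation).
    """
    t = np.asarray(times, float)
    y = np.asarray(angles, float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    failed = SinusoidFit(float("nan"), 0.0, 0.0,
                         float(np.mean(y)) if len(y) else float("nan"),
                         float("nan"), 0.0, False)
    if len(y) < 8:
        return failed
    dt = float(np.median(np.diff(t)))
    if f_bounds is None:
        f_bounds = (0.5, 1.0 / (4.0 * dt))
    sd = float(y.std())
    if sd == 0.0:
        return failed
    if f_init is None or not np.isfinite(f_init):
        f_init = fft_peak_frequency(t, y, f_bounds=f_bounds)
    if not np.isfinite(f_init):
        return failed
    f_init = float(np.clip(f_init, *f_bounds))
    c0 = float(y.mean())
    a0 = sd * np.sqrt(2.0)
    # phase by quadrature projection at the initial frequency
    w0 = 2.0 * np.pi * f_init
    s_proj = np.sum((y - c0) * np.sin(w0 * t))
    c_proj = np.sum((y - c0) * np.cos(w0 * t))
    phi0 = float(np.arctan2(c_proj, s_proj))

    def model(params, tt):
        a, f, phi, c = params
        return a * np.sin(2.0 * np.pi * f * tt + phi) + c

    def resid(params):
        return model(params, t) - y

    lo = [0.0, f_bounds[0], -2.0 * np.pi, -np.inf]
    hi = [np.inf, f_bounds[1], 2.0 * np.pi, np.inf]
    try:
        res = optimize.least_squares(
            resid, x0=[a0, f_init, phi0, c0], bounds=(lo, hi),
            xtol=1e-12, ftol=1e-12, gtol=1e-12)
    except Exception:
        return failed
    a, f, phi, c = res.x
    if a < 0:
        a, phi = -a, phi + np.pi
    phi = float(_wrap(phi))
    rss = float(np.sum(res.fun ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    r2 = float(min(max(r2, 0.0), 1.0))
    resid_rms = np.sqrt(rss / len(y))
    if not res.success or a < noise_floor_factor * resid_rms:
        return SinusoidFit(float("nan"), float(a), phi, float(c), rss, r2, False)
    return SinusoidFit(float(f), float(a), phi, float(c), rss, r2, True)


def frequency_series(angles: AngleSeries, fps: float | None = None,
                     window_s: float = 0.5,
                     events: list[int] | None = None,
                     min_window_fraction: float = 0.75) -> BeatFrequencySeries:
    """Fit a sinusoid inside every frame's window of the angle series.

    Window or fit failures are recorded as per-frame gaps with a status
    string; they never abort the whole series.  Windows drop gap (NaN)
    frames; a window retaining fewer than ``min_window_fraction`` of its N
    samples is itself treated as a gap.
    """
    fps = angles.fps if fps is None else fps
    events = list(angles.event_frames) if events is None else list(events)
    n = len(angles)
    N = window_size(fps, window_s)
    freq = np.full(n, np.nan)
    amp = np.full(n, np.nan)
    r2 = np.full(n, np.nan)
    wstart = np.full(n, -1, dtype=int)
    wend = np.full(n, -1, dtype=int)
    status: list[str] = []
    for k in range(n):
        try:
            a, b = window_bounds(k, n, fps, window_s, events)
        except WindowError as exc:
            status.append(f"window: {exc}")
            continue
        wstart[k], wend[k] = a, b
        tt = angles.times[a:b]
        yy = angles.angles[a:b]
        good = np.isfinite(yy)
        if good.sum() < max(int(min_window_fraction * N), 8):
            status.append(f"gap: only {int(good.sum())}/{N} samples")
            continue
        fit = fit_sinusoid(tt[good], yy[good])
        if not fit.converged:
            status.append("fit failed")
            amp[k], r2[k] = fit.amplitude, fit.r_squared
            continue
        freq[k] = fit.frequency
        amp[k] = fit.amplitude
        r2[k] = fit.r_squared
        status.append("ok")
    return BeatFrequencySeries(
        frame=np.arange(n), time_s=np.asarray(angles.times, float),
        frequency_hz=freq, amplitude_rad=amp, r_squared=r2,
        window_start=wstart, window_end=wend, status=status)


def moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Plain centred moving average for display.

    This is a generic smoother for plots; it is not equivalent to the
    proprietary display smoothing some plotting packages apply.
    """
    values = np.asarray(values, float)
    if width <= 1:
        return values.copy()
    out = np.full_like(values, np.nan)
    half = width // 2
    for i in range(len(values)):
        seg = values[max(0, i - half):i + half + 1]
        seg = seg[np.isfinite(seg)]
        if len(seg):
            out[i] = seg.mean()
    return out
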