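"""Sliding analysis-window bookkeeping shared by tracking and frequency fitting.

Every per-frame quantity (symmetry axis, beat frequency) is measured inside a
window of 0.5 s before and after the frame.  Windows always contain the same
number of frames N = 2*round(window_s*fps) + 1: at the start or end of the
video, or flanking a light-flash frame, the window is shifted toward the
interior instead of shrinking, and it never mixes frames from both sides of
an event.  The event frame index marks the first post-flash frame and belongs
to the post-event regime.
"""

from __future__ import annotations

from typing import Sequence


class WindowError(ValueError):
    """Raised when no valid fixed-size window exists for a frame."""


def window_size(fps: float, window_s: float) -> int:
    """N = centre frame plus ``window_s`` of frames on each side."""
    return 2 * int(round(window_s * fps)) + 1


def window_bounds(frame: int, n_frames: int, fps: float, window_s: float,
                  events: Sequence[int] = ()) -> tuple[int, int]:
    """Half-open ``[start, end)`` of exactly N frames containing ``frame``.

    The window is centred on ``frame`` when possible and otherwise shifted
    minimally toward the interior of the event-free run containing ``frame``.

    Raises
    ------
    WindowError
        If the event-free run containing ``frame`` is shorter than N frames.
    """
    if not (0 <= frame < n_frames):
        raise ValueError(f"frame {frame} outside [0, {n_frames})")
    n = window_size(fps, window_s)
    bounds = sorted({0, n_frames, *(e for e in events if 0 < e < n_frames)})
    lo, hi = 0, n_frames
    for a, b in zip(bounds[:-1], bounds[1:]):
        if a <= frame < b:
            lo, hi = a, b
            break
    if hi - lo < n:
        raise WindowError(
            f"frame {frame}: event-free run [{lo}, {hi}) holds only "
            f"{hi - lo} frames, need {n}")
    start = frame - n // 2
    start = max(lo, min(start, hi - n))
    return start, start + n
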