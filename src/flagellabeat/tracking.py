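"""Per-frame segmentation, flagellum tracing and head-midflagellum angles.

The quantity driving the beat-frequency estimate is the signed angle between
the straight line joining the head centre to the middle of the flagellum and
the cell's symmetry axis.  For a beating tethered cell this angle oscillates
in a sinusoid-like manner.  The symmetry axis is not directly observable; it
is estimated as the circular mean of the head-to-midpoint directions over the
same sliding window used for the frequency fit, on the grounds that the beat
oscillates symmetrically about the cell axis.

Coordinate conventions: pixel centres at integer coordinates, origin top-left,
x right, y down in storage; angles are computed after mapping to a y-up
mathematical frame, so positive angles are counter-clockwise.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from skimage import filters, measure, morphology
from scipy import ndimage

from .windows import WindowError, window_bounds

__all__ = [
    "VideoStack", "FlagellumTrace", "HeadPose", "AngleSeries",
    "SegmentationError", "TracingError", "TrackingLostError",
    "binarize", "locate_head", "trace_flagellum", "midpoint",
    "symmetry_axis", "angle_series",
]


class SegmentationError(ValueError):
    pass


class TracingError(ValueError):
    pass


class TrackingLostError(ValueError):
    pass


@dataclass
class VideoStack:
    """Ordered grayscale frames with acquisition metadata."""

    frames: np.ndarray  # (n, h, w)
    fps: float
    um_per_px: float
    event_frames: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if self.fps <= 0 or self.um_per_px <= 0:
            raise ValueError("fps and um_per_px must be positive")
        ev = list(self.event_frames)
        if ev != sorted(set(ev)) or any(
                not (0 <= e < len(self.frames)) for e in ev):
            raise ValueError("event_frames must be strictly increasing and in range")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class HeadPose:
    frame_index: int
    center: tuple[float, float]
    confidence: float = 1.0


@dataclass
class FlagellumTrace:
    """Ordered skeleton path, head end first, in storage pixel coordinates."""

    frame_index: int
    points: np.ndarray  # (n, 2) as (x, y)
    arc_length_px: float


@dataclass
class AngleSeries:
    """Signed head-midflagellum angles about a windowed symmetry axis."""

    times: np.ndarray
    angles: np.ndarray            # radians in (-pi, pi]; NaN marks a gap
    axis_rad: np.ndarray          # per-frame symmetry-axis direction used
    fps: float = 200.0
    event_frames: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.angles)


def _wrap(a):
    return -((-np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi)


def binarize(frame: np.ndarray, min_foreground_px: int = 20,
             frame_index: int | None = None) -> np.ndarray:
    """Threshold the frame automatically and keep the largest component.

    The threshold core is Otsu's between-class-variance criterion on the
    frame histogram.  Because the flagellum is a Gaussian-profile ridge, a
    single Otsu cut clips its dim flanks, so the Otsu level is used as the
    strong threshold of a hysteresis pair: pixels above the midpoint between
    the background level (the frame median) and the Otsu level are kept when
    connected to an above-Otsu core.  Isolated noise stays out because it
    never touches the core.
    """
    frame = np.asarray(frame)
    tag = "" if frame_index is None else f" (frame {frame_index})"
    if frame.std() == 0:
        raise SegmentationError(f"zero-variance frame{tag}")
    strong = filters.threshold_otsu(frame)
    bg = float(np.median(frame))
    weak = bg + 0.5 * (float(strong) - bg)
    fg = filters.apply_hysteresis_threshold(frame, weak, strong)
    if fg.sum() < min_foreground_px:
        raise SegmentationError(
            f"foreground below {min_foreground_px} px{tag}")
    labels = measure.label(fg, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    out = labels == largest
    if out.sum() < min_foreground_px:
        raise SegmentationError(
            f"largest component below {min_foreground_px} px{tag}")
    # noise pinholes in the ridge would turn the skeleton into a loop
    return ndimage.binary_fill_holes(out)


def locate_head(binary: np.ndarray, prior: tuple[float, float] | None = None,
                intensity: np.ndarray | None = None,
                search_radius_px: float = 20.0,
                frame_index: int = 0) -> HeadPose:
    """Head centre as the weighted centroid of the widest region of the cell.

    The head is the locally widest (and in dark-field brightest) part of the
    component, found where the distance transform is close to its maximum.
    With a ``prior`` the search is restricted to a window around it.
    """
    binary = np.asarray(binary, bool)
    if not binary.any():
        raise TrackingLostError(f"empty foreground (frame {frame_index})")
    region = binary
    if prior is not None:
        h, w = binary.shape
        yy, xx = np.mgrid[0:h, 0:w]
        near = np.hypot(xx - prior[0], yy - prior[1]) <= search_radius_px
        region = binary & near
        if not region.any():
            raise TrackingLostError(
                f"no foreground within {search_radius_px} px of the prior "
                f"(frame {frame_index})")
    dt = ndimage.distance_transform_edt(region)
    head_blob = dt >= 0.6 * dt.max()
    weights = dt[head_blob] if intensity is None else (
        np.asarray(intensity, float)[head_blob] * dt[head_blob])
    rows, cols = np.nonzero(head_blob)
    cx = float(np.average(cols, weights=weights))
    cy = float(np.average(rows, weights=weights))
    return HeadPose(frame_index=frame_index, center=(cx, cy), confidence=1.0)


# -- skeleton graph helpers -------------------------------------------------

_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbors(skel: np.ndarray, r: int, c: int):
    h, w = skel.shape
    for dr, dc in _NBRS:
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w and skel[rr, cc]:
            yield rr, cc


_RING = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _crossing_runs(skel: np.ndarray) -> np.ndarray:
    """Connected runs of skeleton pixels around each pixel's 8-neighbour ring.

    One run marks a line end, two a mid-line pixel, three or more a branch
    point.  Unlike the plain neighbour count this stays correct at staircase
    corners, where a geometric endpoint can have two mutually adjacent
    neighbours.
    """
    h, w = skel.shape
    ring = np.zeros((8, h, w), dtype=bool)
    for i, (dr, dc) in enumerate(_RING):
        src = np.zeros_like(skel)
        r0, r1 = max(dr, 0), h + min(dr, 0)
        c0, c1 = max(dc, 0), w + min(dc, 0)
        src[r0 - dr:r1 - dr, c0 - dc:c1 - dc] = skel[r0:r1, c0:c1]
        ring[i] = src
    rolled = np.roll(ring, 1, axis=0)
    runs = np.sum(ring & ~rolled, axis=0)
    # a fully surrounded pixel (no transitions) counts as one run
    runs[(runs == 0) & ring.any(axis=0)] = 1
    return np.where(skel, runs, 0)


def _prune_spurs(skel: np.ndarray, prune_len: float) -> np.ndarray:
    """Iteratively delete endpoint twigs shorter than ``prune_len`` px.

    From every line end the skeleton is walked inward; if a junction (a
    branch pixel, or a pixel with several onward continuations) is reached
    before ``prune_len`` px, the walked twig is deleted.  One twig is removed
    per pass so the topology stays current.
    """
    skel = skel.copy()
    while True:
        runs = _crossing_runs(skel)
        endpoints = list(zip(*np.nonzero(runs == 1)))
        pruned = False
        for e in endpoints:
            path = [e]
            visited = {e}
            cur = e
            length = 0.0
            hit_branch = False
            while length < prune_len:
                nbrs = [p for p in _neighbors(skel, *cur) if p not in visited]
                if len(nbrs) == 0:
                    break
                if len(nbrs) > 1:  # junction just past cur
                    hit_branch = True
                    break
                nxt = nbrs[0]
                if runs[nxt] >= 3:
                    hit_branch = True
                    break
                length += np.hypot(nxt[0] - cur[0], nxt[1] - cur[1])
                path.append(nxt)
                visited.add(nxt)
                cur = nxt
            if hit_branch and length < prune_len:
                for p in path:
                    skel[p] = False
                pruned = True
                break
        if not pruned:
            break
    return skel


def _skeleton_path(skel: np.ndarray, start: tuple[int, int],
                   goal: tuple[int, int]) -> list[tuple[int, int]]:
    """BFS path between two skeleton pixels (8-connected)."""
    prev: dict = {start: None}
    q = deque([start])
    while q:
        cur = q.popleft()
        if cur == goal:
            break
        for nb in _neighbors(skel, *cur):
            if nb not in prev:
                prev[nb] = cur
                q.append(nb)
    if goal not in prev:
        raise TracingError("skeleton endpoints are not connected")
    path = [goal]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    return path[::-1]


def trace_flagellum(binary: np.ndarray, head: HeadPose,
                    prune_len_px: float = 5.0,
                    trim_head: bool = True) -> FlagellumTrace:
    """Skeletonize the cell and order the skeleton from head end to tip.

    Spurs shorter than ``prune_len_px`` (head-blob artefacts, noise twigs)
    are pruned; the remaining path is ordered from the skeleton endpoint
    nearest the head centre to the farthest endpoint.  When the component
    carries a distinct head blob (its inradius clearly exceeding the ridge
    half-width) the initial path run inside that blob is trimmed, so the
    trace covers the flagellum proper rather than the head interior.
    """
    binary = np.asarray(binary, bool)
    skel = morphology.skeletonize(binary)
    skel = _prune_spurs(skel, prune_len_px)
    runs = _crossing_runs(skel)
    n_pix = int(skel.sum())
    if n_pix < 2:
        raise TracingError("skeleton too short to trace")
    endpoints = list(zip(*np.nonzero(runs == 1)))
    if len(endpoints) == 0:
        raise TracingError("skeleton has no endpoints (closed loop)")
    if len(endpoints) == 1:
        raise TracingError("skeleton has a single endpoint (loop with a tail)")
    if len(endpoints) > 2:
        raise TracingError(
            f"skeleton has {len(endpoints)} endpoints after pruning")
    hx, hy = head.center
    # head-end endpoint: nearest to the head centre; ties by lower index
    d = [np.hypot(c - hx, r - hy) for r, c in endpoints]
    start = endpoints[int(np.argmin(d))]
    goal = endpoints[1 - int(np.argmin(d))]
    path = _skeleton_path(skel, start, goal)
    pts = np.array([(c, r) for r, c in path], dtype=float)
    if trim_head and len(pts) > 4:
        dt = ndimage.distance_transform_edt(binary)
        inradius = float(dt.max())
        # ridge half-width from the distal half of the path
        cols = np.clip(np.round(pts[:, 0]).astype(int), 0, binary.shape[1] - 1)
        rows = np.clip(np.round(pts[:, 1]).astype(int), 0, binary.shape[0] - 1)
        half_width = float(np.median(dt[rows, cols][len(pts) // 2:]))
        if inradius > 2.5 * half_width:
            dh = np.hypot(pts[:, 0] - hx, pts[:, 1] - hy)
            outside = np.nonzero(dh >= inradius)[0]
            if len(outside) and outside[0] < len(pts) - 2:
                pts = pts[outside[0]:]
    seg = np.diff(pts, axis=0)
    arc = float(np.hypot(seg[:, 0], seg[:, 1]).sum()) if len(pts) > 1 else 0.0
    return FlagellumTrace(frame_index=head.frame_index, points=pts,
                          arc_length_px=arc)


def midpoint(trace: FlagellumTrace) -> tuple[float, float]:
    """Point at half the trace's arc length, interpolated between samples."""
    pts = trace.points
    if len(pts) == 1:
        return float(pts[0, 0]), float(pts[0, 1])
    seg = np.diff(pts, axis=0)
    slen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(slen)])
    half = cum[-1] / 2.0
    i = min(max(int(np.searchsorted(cum, half)) - 1, 0), len(slen) - 1)
    frac = (half - cum[i]) / slen[i] if slen[i] > 0 else 0.0
    p = pts[i] + frac * seg[i]
    return float(p[0]), float(p[1])


def symmetry_axis(directions) -> float:
    """Circular mean of head-to-midpoint directions (radians)."""
    directions = np.asarray(directions, float)
    directions = directions[np.isfinite(directions)]
    if len(directions) == 0:
        raise ValueError("no directions to average")
    z = np.exp(1j * directions).mean()
    if abs(z) < 1e-9:
        raise ValueError("directions have zero resultant; axis undefined")
    return float(np.angle(z))


def _head_mid_direction(video: VideoStack, k: int,
                        prior: tuple[float, float] | None,
                        prune_len_px: float):
    """Head-to-midpoint direction (y-up) for one frame; returns (theta, head)."""
    fg = binarize(video.frames[k], frame_index=k)
    head = locate_head(fg, prior=prior, intensity=video.frames[k],
                       frame_index=k)
    trace = trace_flagellum(fg, head, prune_len_px=prune_len_px)
    mx, my = midpoint(trace)
    hx, hy = head.center
    theta = float(np.arctan2(-(my - hy), mx - hx))  # y-up convention
    return theta, head


def angle_series(video: VideoStack, window_s: float = 0.5,
                 prune_len_px: float = 5.0,
                 max_failed_fraction: float = 0.10) -> AngleSeries:
    """Signed head-midflagellum angle about the windowed symmetry axis.

    Per frame the raw head-to-midpoint direction is measured; the symmetry
    axis is the circular mean of those directions over that frame's analysis
    window (which never crosses a light-flash event), and the reported angle
    is the wrapped difference.  Frames where segmentation or tracing fails
    carry NaN and are excluded from any window average or fit.
    """
    n = len(video)
    directions = np.full(n, np.nan)
    failures: list[tuple[int, str]] = []
    prior = None
    for k in range(n):
        try:
            theta, head = _head_mid_direction(video, k, prior, prune_len_px)
            directions[k] = theta
            prior = head.center
        except (SegmentationError, TracingError, TrackingLostError) as exc:
            failures.append((k, str(exc)))
    if len(failures) > max_failed_fraction * n:
        detail = "; ".join(f"frame {k}: {msg}" for k, msg in failures[:10])
        raise RuntimeError(
            f"tracking failed on {len(failures)}/{n} frames "
            f"(> {max_failed_fraction:.0%}): {detail}")

    angles = np.full(n, np.nan)
    axis = np.full(n, np.nan)
    for k in range(n):
        if not np.isfinite(directions[k]):
            continue
        try:
            a, b = window_bounds(k, n, video.fps, window_s,
                                 video.event_frames)
        except WindowError:
            continue
        local = directions[a:b]
        local = local[np.isfinite(local)]
        if len(local) == 0:
            continue
        axis[k] = symmetry_axis(local)
        angles[k] = _wrap(directions[k] - axis[k])
    times = np.arange(n) / video.fps
    return AngleSeries(times=times, angles=angles, axis_rad=axis,
                       fps=video.fps, event_frames=list(video.event_frames))
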