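"""Stop-motion flagellar-envelope construction.

Each frame is registered on the sperm head, the direction at which the
flagellum emerges from the head (the neck azimuth) is measured inside an
annulus mask centred on the head (internal diameter 16 um, external 20 um —
wide enough to cover the head and resolve the first pixels of the neck), and
every frame is translated to a common head position and rotated by its neck
azimuth before superposition.  The resulting envelope shows the spatial
extent swept by the flagellum over one beating cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import registration, transform

from .tracking import HeadPose, TrackingLostError, VideoStack, binarize

__all__ = [
    "Annulus", "EnvelopeImage", "NeckAzimuthError",
    "register_head", "neck_azimuth", "align_and_superimpose",
]


class NeckAzimuthError(ValueError):
    pass


@dataclass
class Annulus:
    """Ring mask centred on the head used to isolate the neck pixels."""

    center: tuple[float, float]
    inner_diameter_um: float = 16.0
    outer_diameter_um: float = 20.0

    def __post_init__(self):
        if not (self.outer_diameter_um > self.inner_diameter_um > 0):
            raise ValueError("need outer_diameter > inner_diameter > 0")

    def mask(self, shape: tuple[int, int], um_per_px: float) -> np.ndarray:
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        d = np.hypot(xx - self.center[0], yy - self.center[1])
        r_in = self.inner_diameter_um / (2.0 * um_per_px)
        r_out = self.outer_diameter_um / (2.0 * um_per_px)
        if (self.center[0] - r_out < -0.5 or self.center[0] + r_out > w - 0.5
                or self.center[1] - r_out < -0.5
                or self.center[1] + r_out > h - 0.5):
            raise ValueError("annulus does not fit inside the image")
        return (d >= r_in) & (d <= r_out)


@dataclass
class EnvelopeImage:
    image: np.ndarray
    n_frames_used: int
    reference_azimuth: float
    projection: str  # max | mean
    reference_center: tuple[float, float] = (0.0, 0.0)


def _extract_patch(frame: np.ndarray, center: tuple[float, float],
                   radius: int) -> np.ndarray:
    h, w = frame.shape
    cx, cy = int(round(center[0])), int(round(center[1]))
    r = int(radius)
    x0, x1 = cx - r, cx + r + 1
    y0, y1 = cy - r, cy + r + 1
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValueError("ROI extends beyond the image")
    return frame[y0:y1, x0:x1].astype(float), (cx, cy)


def register_head(video: VideoStack, initial_roi: tuple[float, float, float],
                  min_confidence: float = 0.3) -> list[HeadPose]:
    """Track the head by cross-correlation registration of the ROI patch.

    The template is the ROI patch of frame 0; each subsequent frame is
    searched in a window centred on the previous estimate and registered to
    the template by phase cross-correlation with sub-pixel refinement.
    Both patches are apodized with a Gaussian window so the beating
    flagellum entering the patch rim does not bias the head shift.
    Confidence is the normalized match score (1 - registration error).
    """
    cx, cy, radius = initial_roi
    frame0 = video.frames[0].astype(float)
    template, _ = _extract_patch(frame0, (cx, cy), radius)
    if template.std() == 0 or template.max() <= np.median(frame0):
        raise TrackingLostError("initial ROI does not contain the head (frame 0)")
    # refine the starting centre to the brightest-blob centroid inside the ROI
    fg = binarize(video.frames[0], frame_index=0)
    h, w = fg.shape
    yy, xx = np.mgrid[0:h, 0:w]
    inroi = fg & (np.hypot(xx - cx, yy - cy) <= radius)
    if not inroi.any():
        raise TrackingLostError("initial ROI does not contain the head (frame 0)")

    poses = [HeadPose(frame_index=0, center=(float(cx), float(cy)),
                      confidence=1.0)]
    template, t_origin = _extract_patch(frame0, (cx, cy), radius)
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    apod = np.exp(-0.5 * (np.hypot(xx, yy) / (radius / 2.0)) ** 2)
    template = template * apod
    for k in range(1, len(video)):
        prev = poses[-1].center
        patch, p_origin = _extract_patch(video.frames[k].astype(float),
                                         prev, radius)
        shift, error, _ = registration.phase_cross_correlation(
            template, patch * apod, upsample_factor=50, normalization=None)
        conf = float(max(0.0, 1.0 - error))
        if conf < min_confidence:
            raise TrackingLostError(
                f"head lost at frame {k}: match score {conf:.2f}")
        # patch shifted by `shift` (row, col) aligns with the template, so the
        # head in frame k sits at the patch origin minus that shift, offset by
        # where the template origin sat relative to the frame-0 centre
        center = (p_origin[0] - shift[1] + (cx - t_origin[0]),
                  p_origin[1] - shift[0] + (cy - t_origin[1]))
        poses.append(HeadPose(frame_index=k,
                              center=(float(center[0]), float(center[1])),
                              confidence=conf))
    return poses


def neck_azimuth(binary: np.ndarray, head: HeadPose, annulus: Annulus | None,
                 um_per_px: float) -> float:
    """Direction (y-up radians) of the flagellar neck from the head centre.

    The azimuth is the angle of the centroid of foreground pixels inside the
    annulus, measured from the head centre.  Foreground split into two
    opposite sectors (a loop crossing the ring) is rejected as ambiguous.
    """
    if annulus is None:
        annulus = Annulus(center=head.center)
    mask = annulus.mask(binary.shape, um_per_px)
    sel = np.asarray(binary, bool) & mask
    if not sel.any():
        raise NeckAzimuthError(
            f"no foreground inside the annulus (frame {head.frame_index})")
    rows, cols = np.nonzero(sel)
    hx, hy = head.center
    angles = np.arctan2(-(rows - hy), cols - hx)
    resultant = np.abs(np.exp(1j * angles).mean())
    if resultant < 0.3:
        raise NeckAzimuthError(
            f"foreground in opposing sectors of the annulus "
            f"(frame {head.frame_index}); neck direction ambiguous")
    cx = cols.mean()
    cy = rows.mean()
    return float(np.arctan2(-(cy - hy), cx - hx))


def _align_one(frame: np.ndarray, center: tuple[float, float],
               ref_center: tuple[float, float], rot_rad: float) -> np.ndarray:
    """Translate ``center`` to ``ref_center`` and rotate by ``rot_rad``
    (positive counter-clockwise in the y-up frame) about the reference centre."""
    # y-down storage: a CCW y-up rotation is a CW rotation of storage coords
    c, s = np.cos(rot_rad), np.sin(rot_rad)
    # inverse map: output (x,y) -> input coordinates
    tform = (transform.AffineTransform(translation=(-ref_center[0],
                                                    -ref_center[1]))
             + transform.AffineTransform(matrix=np.array([
                 [c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]))
             + transform.AffineTransform(translation=center))
    return transform.warp(frame.astype(float), tform, order=1,
                          preserve_range=True, cval=0.0)


def align_and_superimpose(video: VideoStack, heads: list[HeadPose | None],
                          azimuths: list[float | None],
                          projection: str = "max",
                          reference_center: tuple[float, float] | None = None
                          ) -> EnvelopeImage:
    """Rotate every frame to a common neck orientation and superimpose.

    Each frame is translated so the head sits at the reference centre and
    rotated by ``reference_azimuth - azimuth_k`` (bilinear interpolation);
    frames lacking a pose or azimuth are skipped and counted out.  The
    reference azimuth is that of the first usable frame.
    """
    if projection not in ("max", "mean"):
        raise ValueError("projection must be 'max' or 'mean'")
    if len(heads) != len(video) or len(azimuths) != len(video):
        raise ValueError("need one pose and one azimuth per frame")
    usable = [k for k in range(len(video))
              if heads[k] is not None and azimuths[k] is not None
              and np.isfinite(azimuths[k])]
    if not usable:
        raise ValueError("all frames are gapped; nothing to superimpose")
    ref_az = float(azimuths[usable[0]])
    if reference_center is None:
        reference_center = heads[usable[0]].center
    h, w = video.frames.shape[1:]
    acc = np.zeros((h, w), float)
    for k in usable:
        rot = ref_az - float(azimuths[k])
        aligned = _align_one(video.frames[k], heads[k].center,
                             reference_center, rot)
        if projection == "max":
            acc = np.maximum(acc, aligned)
        else:
            acc += aligned
    if projection == "mean":
        acc /= len(usable)
    return EnvelopeImage(image=acc, n_frames_used=len(usable),
                         reference_azimuth=ref_az, projection=projection,
                         reference_center=(float(reference_center[0]),
                                           float(reference_center[1])))
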