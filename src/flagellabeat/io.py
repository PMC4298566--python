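"""Reading and writing videos, metadata sidecars and stage outputs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .tracking import AngleSeries, VideoStack

__all__ = [
    "write_video", "read_video", "write_angle_series", "read_angle_series",
    "write_json",
]


def write_video(stack: VideoStack, tiff_path, meta_path=None) -> None:
    """Multi-page TIFF plus a YAML sidecar carrying fps, um/px and events."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.frames)
    if meta_path is None:
        meta_path = tiff_path.with_suffix(".yaml")
    meta = {"fps": float(stack.fps), "um_per_px": float(stack.um_per_px),
            "event_frames": [int(e) for e in stack.event_frames]}
    Path(meta_path).write_text(yaml.safe_dump(meta))


def read_video(tiff_path, meta_path=None) -> VideoStack:
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    if meta_path is None:
        meta_path = tiff_path.with_suffix(".yaml")
    meta = yaml.safe_load(Path(meta_path).read_text())
    return VideoStack(frames=frames, fps=float(meta["fps"]),
                      um_per_px=float(meta["um_per_px"]),
                      event_frames=list(meta.get("event_frames", []) or []))


def write_angle_series(series: AngleSeries, path) -> None:
    pd.DataFrame({
        "frame": np.arange(len(series)),
        "time_s": series.times,
        "angle_rad": series.angles,
        "axis_rad": series.axis_rad,
    }).to_csv(path, index=False)


def read_angle_series(path, fps: float,
                      event_frames: list[int] | None = None) -> AngleSeries:
    df = pd.read_csv(path)
    return AngleSeries(times=df["time_s"].to_numpy(float),
                       angles=df["angle_rad"].to_numpy(float),
                       axis_rad=df["axis_rad"].to_numpy(float),
                       fps=fps, event_frames=list(event_frames or []))


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
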