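"""End-to-end pipeline: synthesize (optional) -> track -> beatfreq -> envelope.

A single YAML config drives every stage; each run directory receives the
stage outputs plus a manifest recording package version, parameters, seed and
per-stage status, so identical config + seed reproduces identical numeric
outputs.
"""

from __future__ import annotations

import logging
import traceback
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import yaml

from . import io as fio
from .beat_frequency import frequency_series
from .synthetic_data import (BeatProtocol, FrequencyProfile, RenderParams,
                             generate_video)
from .tracking import angle_series, binarize, locate_head
from .waveform_alignment import (Annulus, NeckAzimuthError, align_and_superimpose,
                                 neck_azimuth, register_head)

log = logging.getLogger("flagellabeat")

__all__ = ["load_config", "run_pipeline", "frequency_profile_from_config",
           "protocol_from_config", "render_from_config"]


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def frequency_profile_from_config(spec: dict) -> FrequencyProfile:
    kind = spec.get("kind", "constant")
    if kind == "constant":
        return FrequencyProfile.constant(float(spec["f"]))
    if kind == "step":
        return FrequencyProfile.step(float(spec["f1"]), float(spec["f2"]),
                                     float(spec["t"]))
    raise ConfigError(f"unknown frequency kind {kind!r}")


def protocol_from_config(spec: dict, seed: int = 0) -> BeatProtocol:
    freq = frequency_profile_from_config(spec.get("frequency", {"f": 10.0}))
    keys = ("duration_s", "fps", "event_time_s", "amplitude_rad",
            "wavelength_um", "flagellum_length_um", "base_orientation_rad",
            "rotation_rad_per_frame")
    kwargs = {k: spec[k] for k in keys if k in spec}
    if "head_center_px" in spec:
        kwargs["head_center_px"] = tuple(spec["head_center_px"])
    if "drift_px_per_frame" in spec:
        kwargs["drift_px_per_frame"] = tuple(spec["drift_px_per_frame"])
    return BeatProtocol(frequency_fn=freq, seed=seed, **kwargs)


def render_from_config(spec: dict, seed: int = 0) -> RenderParams:
    keys = ("um_per_px", "background_level", "flagellum_peak",
            "line_sigma_px", "head_radius_um", "noise_sigma")
    kwargs = {k: spec[k] for k in keys if k in spec}
    if "image_size_px" in spec:
        kwargs["image_size_px"] = tuple(spec["image_size_px"])
    return RenderParams(seed=seed, **kwargs)


def _summarize(freqs: np.ndarray, events: list[int]) -> dict:
    good = np.isfinite(freqs)
    out = {"n_frames": int(len(freqs)), "n_estimated": int(good.sum()),
           "mean_frequency_hz": float(np.nanmean(freqs)) if good.any() else None}
    if events:
        e = events[0]
        pre = freqs[:e][np.isfinite(freqs[:e])]
        post = freqs[e:][np.isfinite(freqs[e:])]
        if len(pre) and len(post):
            out["pre_event_mean_hz"] = float(pre.mean())
            out["post_event_mean_hz"] = float(post.mean())
            out["fold_change"] = float(post.mean() / pre.mean())
    return out


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute all configured stages; returns the manifest dict.

    Any stage error is recorded in the manifest (status ``failed``) and the
    manifest's ``ok`` flag cleared; downstream stages that depend on the
    failed one are skipped.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {"package": "flagellabeat",
                      "version": _pkg_version("flagellabeat"),
                      "seed": seed, "config": config, "stages": {},
                      "outputs": [], "ok": True}

    def record(stage: str, status: str, files: list[str] = (), **extra):
        manifest["stages"][stage] = {"status": status, **extra}
        manifest["outputs"].extend(files)
        if status == "failed":
            manifest["ok"] = False

    video = None
    truth = None
    # --- synthesize or load -------------------------------------------------
    try:
        if "synthesize" in config:
            protocol = protocol_from_config(config["synthesize"], seed=seed)
            render = render_from_config(config["synthesize"].get("render", {}),
                                        seed=seed)
            video, truth = generate_video(protocol, render)
            fio.write_video(video, out_dir / "video.tif",
                            out_dir / "video.yaml")
            truth.to_csv(out_dir / "ground_truth.csv")
            record("synthesize", "completed",
                   ["video.tif", "video.yaml", "ground_truth.csv"],
                   n_frames=len(video))
        elif "video" in config:
            vpath = Path(config["video"])
            mpath = Path(config["meta"]) if "meta" in config else None
            if not vpath.exists() or (mpath is not None and not mpath.exists()):
                raise ConfigError(f"video/meta path missing: {vpath}")
            video = fio.read_video(vpath, mpath)
            record("synthesize", "skipped")
        else:
            raise ConfigError("config needs either 'synthesize' or 'video'")
    except ConfigError:
        raise
    except Exception as exc:
        log.error("synthesize failed: %s", exc)
        record("synthesize", "failed", error=str(exc),
               trace=traceback.format_exc(limit=3))

    # --- track --------------------------------------------------------------
    angles = None
    track_cfg = config.get("track", {})
    if video is not None:
        try:
            angles = angle_series(video,
                                  window_s=float(track_cfg.get("window_s", 0.5)),
                                  prune_len_px=float(
                                      track_cfg.get("prune_len_px", 5.0)))
            fio.write_angle_series(angles, out_dir / "angles.csv")
            record("track", "completed", ["angles.csv"],
                   n_gaps=int(np.sum(~np.isfinite(angles.angles))))
        except Exception as exc:
            log.error("track failed: %s", exc)
            record("track", "failed", error=str(exc))
    else:
        record("track", "skipped")

    # --- beat frequency -----------------------------------------------------
    if angles is not None:
        try:
            bf_cfg = config.get("beatfreq", {})
            series = frequency_series(angles,
                                      window_s=float(bf_cfg.get("window_s", 0.5)))
            series.to_frame().to_csv(out_dir / "beat_frequency.csv", index=False)
            summary = _summarize(series.frequency_hz, video.event_frames)
            fio.write_json(summary, out_dir / "beat_summary.json")
            record("beatfreq", "completed",
                   ["beat_frequency.csv", "beat_summary.json"], **summary)
        except Exception as exc:
            log.error("beatfreq failed: %s", exc)
            record("beatfreq", "failed", error=str(exc))
    else:
        record("beatfreq", "skipped")

    # --- envelope -----------------------------------------------------------
    if video is not None:
        try:
            env_cfg = config.get("envelope", {})
            if "roi" in env_cfg:
                roi = tuple(float(v) for v in env_cfg["roi"])
            else:
                fg0 = binarize(video.frames[0], frame_index=0)
                head0 = locate_head(fg0, intensity=video.frames[0])
                roi = (*head0.center, float(env_cfg.get("roi_radius_px", 12.0)))
            heads = register_head(video, roi)
            azimuths: list[float | None] = []
            for k, head in enumerate(heads):
                try:
                    fg = binarize(video.frames[k], frame_index=k)
                    azimuths.append(neck_azimuth(
                        fg, head, Annulus(center=head.center),
                        video.um_per_px))
                except (NeckAzimuthError, Exception):
                    azimuths.append(None)
            env = align_and_superimpose(
                video, heads, azimuths,
                projection=env_cfg.get("projection", "max"))
            import tifffile
            tifffile.imwrite(out_dir / "envelope.tif",
                             env.image.astype(np.float32))
            fio.write_json({"n_frames_used": env.n_frames_used,
                            "reference_azimuth_rad": env.reference_azimuth,
                            "projection": env.projection},
                           out_dir / "envelope.json")
            record("envelope", "completed", ["envelope.tif", "envelope.json"],
                   n_frames_used=env.n_frames_used)
        except Exception as exc:
            log.error("envelope failed: %s", exc)
            record("envelope", "failed", error=str(exc))
    else:
        record("envelope", "skipped")

    fio.write_json({k: v for k, v in manifest.items() if k != "config"},
                   out_dir / "manifest.json")
    return manifest
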