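import numpy as np
import pytest

from flagellabeat import BeatProtocol, FrequencyProfile, RenderParams, \
    generate_video


@pytest.fixture(scope="session")
def beat_video_cache():
    """Session cache of rendered synthetic videos keyed by their protocol."""
    cache = {}

    def make(f_hz=10.0, duration_s=2.0, noise_sigma=9.0, seed=0, **kwargs):
        key = (f_hz, duration_s, noise_sigma, seed,
               tuple(sorted(kwargs.items())))
        if key not in cache:
            protocol = BeatProtocol(
                duration_s=duration_s, fps=200.0,
                frequency_fn=FrequencyProfile.constant(f_hz),
                seed=seed, **kwargs)
            render = RenderParams(noise_sigma=noise_sigma, seed=seed)
            cache[key] = generate_video(protocol, render)
        return cache[key]

    return make


@pytest.fixture(scope="session")
def short_video(beat_video_cache):
    """0.4 s noisy 10 Hz recording shared across tracking tests."""
    return beat_video_cache(f_hz=10.0, duration_s=0.4, noise_sigma=9.0)


def analytic_angle_series(protocol: BeatProtocol, um_per_px: float = 0.6875):
    """Head-midflagellum angle series computed straight from the kinematic
    model, bypassing rendering and tracking.  Serves as a fast oracle input
    for the frequency-fitting stage."""
    from flagellabeat import flagellum_curve
    from flagellabeat.synthetic_data import _midpoint_um
    n = protocol.n_frames
    times = np.arange(n) / protocol.fps
    ang = np.empty(n)
    for k, t in enumerate(times):
        mid = _midpoint_um(flagellum_curve(protocol, float(t)))
        ang[k] = np.arctan2(mid[1], mid[0]) - protocol.base_orientation_rad
    return times, ang
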