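"""dF/F0 normalization of calcium-indicator fluorescence traces.

Two baseline (F0) conventions are supported, matching the two instruments a
sperm-physiology lab uses:

* plate reader — F0 is the mean fluorescence before compound addition
  (``pre_event_mean``); compounds are added to the well during the recording
  and the event index marks the first post-addition sample;
* stopped flow — F0 is the mean of the first three data points recorded
  immediately after mixing (``first_three_mean``), when a stable signal is
  first observed.

In both cases dF/F0(%) = 100 * (F - F0) / F0, and a buffer-control dF/F0
trace can be subtracted pointwise from a compound-induced trace.

Plate-reader protocols that alternate excitation wavelengths (e.g. 520 nm to
read the indicator and 485 nm to photo-activate an actuator) are handled by
splitting the interleaved record by excitation tag and normalizing only the
indicator samples; the actuator-excitation samples are book-kept but excluded
from dF/F0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import FluorescenceTrace

__all__ = [
    "FluorescenceTrace", "NormalizedTrace", "NormalizationError",
    "dff0_platereader", "dff0_stoppedflow", "subtract_control",
    "split_by_excitation", "read_trace_csv",
]


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizedTrace:
    times: np.ndarray
    dff0_percent: np.ndarray
    f0: float
    convention: str  # pre_event_mean | first_three_mean
    event_index: int | None = None
    control_subtracted: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times,
                             "dff0_percent": self.dff0_percent})


def dff0_platereader(trace: FluorescenceTrace) -> NormalizedTrace:
    """dF/F0 with F0 = mean fluorescence before compound addition."""
    if trace.instrument != "plate_reader":
        raise ValueError(f"expected a plate_reader trace, got {trace.instrument}")
    ev = trace.event_index
    if ev is None or not (2 <= ev < len(trace.values)):
        raise ValueError("need >= 2 samples before the addition event")
    f0 = float(np.mean(trace.values[:ev]))
    if f0 <= 0:
        raise NormalizationError(f"non-positive baseline F0 = {f0}")
    dff0 = 100.0 * (trace.values - f0) / f0
    return NormalizedTrace(times=trace.times.copy(), dff0_percent=dff0,
                           f0=f0, convention="pre_event_mean",
                           event_index=ev)


def dff0_stoppedflow(trace: FluorescenceTrace) -> NormalizedTrace:
    """dF/F0 with F0 = mean of the first three points after mixing."""
    if trace.instrument != "stopped_flow":
        raise ValueError(f"expected a stopped_flow trace, got {trace.instrument}")
    if len(trace.values) < 3:
        raise ValueError("stopped-flow trace needs at least 3 samples")
    f0 = float(np.mean(trace.values[:3]))
    if f0 <= 0:
        raise NormalizationError(f"non-positive baseline F0 = {f0}")
    dff0 = 100.0 * (trace.values - f0) / f0
    return NormalizedTrace(times=trace.times.copy(), dff0_percent=dff0,
                           f0=f0, convention="first_three_mean",
                           event_index=trace.event_index)


def subtract_control(signal: NormalizedTrace,
                     control: NormalizedTrace) -> NormalizedTrace:
    """Pointwise buffer-control subtraction of two normalized traces."""
    if signal.convention != control.convention:
        raise ValueError("cannot mix F0 conventions in a subtraction")
    if len(signal.times) != len(control.times):
        raise ValueError("signal and control have different lengths")
    if len(signal.times) > 1:
        dt = float(np.median(np.diff(signal.times)))
        if np.max(np.abs(signal.times - control.times)) > dt:
            raise ValueError("signal and control time stamps do not align")
    return NormalizedTrace(
        times=signal.times.copy(),
        dff0_percent=signal.dff0_percent - control.dff0_percent,
        f0=signal.f0, convention=signal.convention,
        event_index=signal.event_index, control_subtracted=True)


def split_by_excitation(times, values, excitation,
                        indicator_nm: float = 520.0):
    """Split an alternating-excitation record into indicator and actuator
    sub-traces; only the indicator samples are meant for dF/F0."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    excitation = np.asarray(excitation, float)
    is_ind = excitation == indicator_nm
    return ((times[is_ind], values[is_ind]),
            (times[~is_ind], values[~is_ind]))


def read_trace_csv(path, instrument: str = "plate_reader",
                   event_index: int | None = None) -> FluorescenceTrace:
    """Read a delimited trace: columns time, value[, excitation_nm]."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    tcol = next(c for c in cols if c.startswith("time"))
    vcol = next(c for c in cols if c.startswith(("value", "intensity", "f")))
    times = df[tcol].to_numpy(float)
    values = df[vcol].to_numpy(float)
    exc = next((c for c in cols if c.startswith("exc")), None)
    if exc is not None:
        (times, values), _ = split_by_excitation(times, values, df[exc])
    return FluorescenceTrace(times=times, values=values,
                             event_index=event_index, instrument=instrument)
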