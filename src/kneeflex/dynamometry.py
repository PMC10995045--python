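"""Dynamometer torque-trace processing and group statistics.

The maximal voluntary contraction (MVC) chain: low-pass filter each trace
at 20 Hz with a zero-lag fourth-order Butterworth filter (a second-order
filter applied forward and backward), take the maximum 500 ms moving
average, subtract the mean baseline over the first 500 ms (which removes
limb weight and passive contributions), keep the maximum across trials,
form the between-leg relative difference against the contralateral leg,
and summarize a group of such differences with a Student-t 95% confidence
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import t as student_t

from .errors import ParameterError, ProtocolError

__all__ = [
    "TorqueTrace",
    "MVCResult",
    "lowpass_filter",
    "lowpass_filter_array",
    "trial_mvc",
    "aggregate_trials",
    "between_leg_diff",
    "group_ci95",
    "ci95_from_stats",
    "process_trials",
    "read_traces_csv",
]

DEFAULT_CUTOFF_HZ = 20.0
WINDOW_S = 0.5
#: Reflection-padding length used by the zero-phase filter, seconds.
PAD_S = 1.0
#: Extra-trial rule: another trial is warranted if the last trial is at
#: least this factor above the best earlier trial.
CONTINUATION_FACTOR = 1.05


@dataclass
class TorqueTrace:
    """A uniformly sampled dynamometer torque recording (Nm)."""

    samples: np.ndarray
    fs: float = 2000.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not (self.fs > 0):
            raise ParameterError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class MVCResult:
    """Processed MVC for one leg at one knee angle."""

    mvc: float
    trial_values: list[float]
    meta: dict = field(default_factory=dict)


def _butter_sos(cutoff_hz: float, fs: float):
    if not (0 < cutoff_hz < fs / 2):
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie below the Nyquist rate {fs / 2} Hz")
    return signal.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")


def lowpass_filter_array(samples: np.ndarray, fs: float,
                         cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> np.ndarray:
    """Zero-phase low-pass filter along the last axis of ``samples``.

    A 2nd-order Butterworth filter applied forward then backward (net
    4th-order magnitude response, zero lag), with reflection padding.
    """
    samples = np.asarray(samples, dtype=float)
    sos = _butter_sos(cutoff_hz, fs)
    padlen = min(int(round(PAD_S * fs)), samples.shape[-1] - 2)
    return signal.sosfiltfilt(sos, samples, axis=-1,
                              padtype="even", padlen=max(padlen, 0))


def lowpass_filter(trace: TorqueTrace,
                   cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> TorqueTrace:
    """Zero-phase low-pass filtered copy of one trace."""
    return TorqueTrace(samples=lowpass_filter_array(trace.samples, trace.fs,
                                                    cutoff_hz),
                       fs=trace.fs, meta=dict(trace.meta))


def trial_mvc(trace: TorqueTrace, window_s: float = WINDOW_S) -> float:
    """Moment value of one (already filtered) trial, Nm.

    Maximum ``window_s`` moving average minus the mean over the first
    ``window_s`` (the pre-contraction baseline); adding a constant offset
    to the whole trace therefore leaves the result unchanged.
    """
    n = trace.samples.size
    win = int(round(window_s * trace.fs))
    if n < 2 * win:
        raise ProtocolError(
            f"trace of {n} samples is shorter than two {window_s} s windows")
    moving = np.convolve(trace.samples, np.full(win, 1.0 / win), mode="valid")
    baseline = float(np.mean(trace.samples[:win]))
    return float(np.max(moving)) - baseline


def aggregate_trials(trial_values) -> tuple[float, bool]:
    """MVC across trials plus the extra-trial continuation flag.

    The MVC is the maximum of all trials.  The protocol requires another
    trial whenever the third or a subsequent trial is at least 5% greater
    than the best of all previous trials; the returned flag is True when
    the last supplied trial fires that rule.
    """
    values = [float(v) for v in trial_values]
    if len(values) < 3:
        raise ProtocolError("at least three trials are required")
    best_previous = max(values[:-1])
    # ratio comparison keeps the inclusive 5% boundary exact in floating point
    cont = (best_previous > 0
            and values[-1] / best_previous >= CONTINUATION_FACTOR - 1e-12)
    return max(values), cont


def between_leg_diff(aclr_nm: float, contra_nm: float) -> float:
    """Relative between-leg difference, (ACLR - contralateral)/contralateral."""
    if not (contra_nm > 0):
        raise ParameterError("contralateral moment must be positive")
    return (aclr_nm - contra_nm) / contra_nm


def group_ci95(values) -> tuple[float, float, float]:
    """Mean and Student-t 95% confidence interval of a sample."""
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 2:
        raise ParameterError("at least two values are required for a CI")
    mean = float(np.mean(arr))
    half = float(student_t.ppf(0.975, n - 1) * np.std(arr, ddof=1) / np.sqrt(n))
    return mean, mean - half, mean + half


def ci95_from_stats(mean: float, sd: float, n: int) -> tuple[float, float]:
    """Student-t 95% CI endpoints from summary statistics."""
    if n < 2:
        raise ParameterError("at least two observations are required")
    half = float(student_t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    return mean - half, mean + half


def process_trials(traces: list[TorqueTrace],
                   cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> MVCResult:
    """Filter each trial, extract its moment, and aggregate to one MVC."""
    values = [trial_mvc(lowpass_filter(tr, cutoff_hz)) for tr in traces]
    mvc, cont = aggregate_trials(values)
    meta = dict(traces[0].meta) if traces else {}
    meta["continuation"] = cont
    return MVCResult(mvc=mvc, trial_values=values, meta=meta)


def read_traces_csv(path) -> list[TorqueTrace]:
    """Read torque traces from CSV.

    Either a two-column file (time_s, torque_Nm) holding one trace, or a
    multi-trace file with meta columns (participant, leg, angle_deg, trial)
    grouping rows into traces.
    """
    frame = pd.read_csv(path)
    cols = set(frame.columns)
    if {"time_s", "torque_Nm"} <= cols and len(cols) == 2:
        fs = 1.0 / float(np.median(np.diff(frame["time_s"].to_numpy())))
        return [TorqueTrace(samples=frame["torque_Nm"].to_numpy(), fs=fs)]
    meta_cols = [c for c in ("participant", "leg", "angle_deg", "trial")
                 if c in cols]
    if not meta_cols or "torque_Nm" not in cols:
        raise ParameterError(
            "CSV must contain (time_s, torque_Nm) or torque_Nm with meta "
            "columns participant/leg/angle_deg/trial")
    traces = []
    for key, grp in frame.groupby(meta_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        fs = (1.0 / float(np.median(np.diff(grp["time_s"].to_numpy())))
              if "time_s" in cols else 2000.0)
        traces.append(TorqueTrace(samples=grp["torque_Nm"].to_numpy(), fs=fs,
                                  meta=dict(zip(meta_cols, key))))
    return traces
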