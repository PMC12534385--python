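"""Pedal-timing metrics from photocell traces or crossing timestamps.

A light barrier at the left pedal produces a voltage trace sampled at
100 Hz; each upward threshold crossing marks one revolution.  From the
crossing times three summaries are derived per subject and session:

* mean speed (Hz): average inverse revolution duration,
* CV: SD of the instantaneous speed divided by the mean speed,
* IBD (inter-beat deviation, s): mean absolute deviation between the
  revolution duration and half the stimulus-onset asynchrony (SOA, 2 s in
  the isochronous condition, so the target duration is 1 s).  When the
  stimulation is self-initiated the stimuli are defined by the pedaling
  itself and the IBD is zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PhotocellTrace",
    "CrossingTimes",
    "MotorSummary",
    "detect_crossings",
    "speed_and_cv",
    "ibd",
    "summarize_session",
    "synthesize_trace",
]

DEFAULT_SOA_S = 2.0
DEFAULT_REFRACTORY_S = 0.25


@dataclass
class PhotocellTrace:
    voltage: np.ndarray
    sample_rate: float = 100.0
    t0: float = 0.0

    def __post_init__(self):
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.voltage)):
            raise ValueError("voltage trace contains non-finite samples")


@dataclass
class CrossingTimes:
    times_s: np.ndarray

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1:
            raise ValueError("times_s must be one-dimensional")
        if len(self.times_s) >= 2 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("crossing times must be strictly increasing")

    @property
    def durations_s(self) -> np.ndarray:
        """Complete revolution durations (first/last partials are unseen)."""
        return np.diff(self.times_s)

    def __len__(self):
        return len(self.times_s)


@dataclass(frozen=True)
class MotorSummary:
    mean_speed_hz: float
    cv: float
    ibd_s: float
    n_revolutions: int
    mode: str
    soa_s: float | None = None


def detect_crossings(
    trace: PhotocellTrace,
    threshold: float | None = None,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> CrossingTimes:
    """Upward threshold crossings with sub-sample linear interpolation.

    ``threshold`` defaults to the midpoint of the trace's peak-to-peak
    range.  Crossings closer than ``refractory_s`` to the previous accepted
    crossing are suppressed (double spikes from bounce or reflections).
    """
    if refractory_s < 0:
        raise ValueError("refractory_s must be >= 0")
    v = trace.voltage
    if threshold is None:
        threshold = 0.5 * (v.min() + v.max())
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    dt = 1.0 / trace.sample_rate
    # linear interpolation between sample idx and idx+1
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    times = trace.t0 + (idx + frac) * dt
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= refractory_s:
            kept.append(t)
            last = t
    if len(kept) < 2:
        raise ValueError(
            f"insufficient events: {len(kept)} crossing(s) detected "
            f"(threshold {threshold:g} V)"
        )
    return CrossingTimes(np.asarray(kept))


def speed_and_cv(times: CrossingTimes) -> tuple:
    """Mean pedaling speed (Hz) and coefficient of variation.

    Speed is the average inverse revolution duration; CV is the sample
    (n-1) standard deviation of the instantaneous speed divided by the
    mean speed.
    """
    d = times.durations_s
    if len(d) < 2:
        raise ValueError("need >= 3 crossing times (>= 2 revolutions)")
    if np.any(d <= 0):
        raise ValueError("nonpositive revolution duration (clock violation)")
    s = 1.0 / d
    mean_speed = float(np.mean(s))
    cv = float(np.std(s, ddof=1) / mean_speed)
    return mean_speed, cv


def ibd(times: CrossingTimes, mode: str, soa_s: float | None = None) -> float:
    """Inter-beat deviation: mean |duration - SOA/2| in isochronous mode;
    identically zero under self-initiated stimulation."""
    if mode == "self_initiated":
        return 0.0
    if mode != "isochronous":
        raise ValueError(f"unknown mode {mode!r}")
    if soa_s is None or soa_s <= 0:
        raise ValueError("isochronous mode requires soa_s > 0")
    d = times.durations_s
    if len(d) < 1:
        raise ValueError("need >= 2 crossing times for IBD")
    return float(np.mean(np.abs(d - soa_s / 2.0)))


def summarize_session(
    times: CrossingTimes, mode: str, soa_s: float | None = DEFAULT_SOA_S
) -> MotorSummary:
    mean_speed, cv = speed_and_cv(times)
    return MotorSummary(
        mean_speed_hz=mean_speed,
        cv=cv,
        ibd_s=ibd(times, mode, soa_s if mode == "isochronous" else None),
        n_revolutions=len(times.durations_s),
        mode=mode,
        soa_s=soa_s if mode == "isochronous" else None,
    )


def synthesize_trace(
    times_s: np.ndarray,
    sample_rate: float = 100.0,
    pulse_s: float = 0.05,
    high_v: float = 5.0,
    low_v: float = 0.0,
) -> PhotocellTrace:
    """Render crossing times as a rectangular photocell voltage trace
    (inverse of :func:`detect_crossings`, for round-trip testing)."""
    times_s = np.asarray(times_s, dtype=float)
    t_end = times_s.max() + 2 * pulse_s
    n = int(np.ceil(t_end * sample_rate)) + 1
    v = np.full(n, low_v)
    for t in times_s:
        i0 = int(np.ceil(t * sample_rate))
        i1 = int(np.ceil((t + pulse_s) * sample_rate))
        v[i0:i1] = high_v
    return PhotocellTrace(voltage=v, sample_rate=sample_rate, t0=0.0)


def summaries_from_table(df: pd.DataFrame, soa_s: float = DEFAULT_SOA_S) -> pd.DataFrame:
    """Motor summaries from a long timestamp table with columns
    (subject_id, session, condition, time_s)."""
    out = []
    for (subj, sess, cond), grp in df.groupby(
        ["subject_id", "session", "condition"], sort=True
    ):
        times = CrossingTimes(np.sort(grp["time_s"].to_numpy()))
        summ = summarize_session(times, mode=cond, soa_s=soa_s)
        out.append(
            {
                "subject_id": subj,
                "session": sess,
                "condition": cond,
                "mean_speed_hz": summ.mean_speed_hz,
                "cv": summ.cv,
                "ibd_s": summ.ibd_s,
                "n_revolutions": summ.n_revolutions,
            }
        )
    return pd.DataFrame(out)
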