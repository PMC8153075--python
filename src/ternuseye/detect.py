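"""Velocity-threshold microsaccade detection.

Velocities are estimated with the standard 5-sample moving-window
estimator; candidates are maximal runs where the horizontal velocity
exceeds lambda times a median-based standard deviation of the session's
horizontal velocities, then filtered by duration (3-110 ms) and a 20-ms
minimum interval to the previous kept event.  An elliptic (2-D) criterion
is available behind a flag, but the default thresholds the horizontal
component only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze_io import GazeRecording

SIGMA_FLOOR = 1e-6  # deg/s; below this the session is unusable for detection


@dataclass
class DetectionParams:
    lambda_threshold: float = 8.0
    min_duration_ms: float = 3.0
    max_duration_ms: float = 110.0
    min_interval_ms: float = 20.0
    velocity_window: int = 5
    use_elliptic: bool = False          # 2-D (vx/sx)^2+(vy/sy)^2 > lambda^2
    interval_rule: str = "offset_to_onset"  # or "onset_to_onset"

    def validate(self) -> None:
        if self.lambda_threshold <= 0:
            raise ValueError("lambda_threshold must be > 0")
        if not (0 < self.min_duration_ms < self.max_duration_ms):
            raise ValueError("need 0 < min_duration < max_duration")
        if self.min_interval_ms < 0:
            raise ValueError("min_interval_ms must be >= 0")
        if self.interval_rule not in ("offset_to_onset", "onset_to_onset"):
            raise ValueError(f"unknown interval_rule {self.interval_rule!r}")


@dataclass
class VelocityStats:
    sigma_x: float
    threshold: float
    degenerate: bool
    sigma_y: float = np.nan


@dataclass
class MicrosaccadeEvent:
    onset_ms: float
    offset_ms: float
    duration_ms: float
    amplitude_deg: float = np.nan
    peak_velocity_deg_s: float = np.nan
    trial_id: int = -1
    session_id: str = ""
    at_edge: bool = False


def compute_velocity(recording: GazeRecording) -> tuple[np.ndarray, np.ndarray]:
    """5-sample window velocity (deg/s) for the horizontal and vertical
    channels: v[n] = (x[n+2] + x[n+1] - x[n-1] - x[n-2]) / (6*dt).

    The first and last two samples are NaN (window incomplete).
    """
    if recording.n_samples < 5:
        raise ValueError("recording shorter than the 5-sample velocity window")
    dt_s = recording.dt_ms / 1000.0

    def est(x):
        v = np.full_like(x, np.nan)
        v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt_s)
        return v

    return est(recording.x_deg), est(recording.y_deg)


def median_sd(velocity: np.ndarray) -> VelocityStats:
    """Median-based standard deviation of one velocity component:
    sigma = sqrt(median(v^2) - median(v)^2), clipped at zero."""
    v = np.asarray(velocity, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no valid velocity samples")
    var = float(np.median(v ** 2) - np.median(v) ** 2)
    sigma = math.sqrt(max(var, 0.0))
    return VelocityStats(sigma_x=sigma, threshold=np.nan,
                         degenerate=sigma < SIGMA_FLOOR)


def session_stats(vx_segments, vy_segments=None,
                  params: DetectionParams | None = None) -> VelocityStats:
    """Pool horizontal (and optionally vertical) velocities over a whole
    session and derive the detection threshold lambda * sigma."""
    params = params or DetectionParams()
    vx = np.concatenate([np.asarray(v, dtype=float) for v in vx_segments])
    stats = median_sd(vx)
    stats.threshold = params.lambda_threshold * stats.sigma_x
    if vy_segments is not None:
        vy = np.concatenate([np.asarray(v, dtype=float) for v in vy_segments])
        stats.sigma_y = median_sd(vy).sigma_x
    return stats


def detect_candidates(vx: np.ndarray, stats: VelocityStats,
                      params: DetectionParams | None = None,
                      time_ms: np.ndarray | None = None,
                      dt_ms: float = 2.0,
                      vy: np.ndarray | None = None) -> list[MicrosaccadeEvent]:
    """Maximal supra-threshold runs of the (horizontal) velocity.

    A run must last at least ceil(min_duration/dt) samples.  Onset is the
    first sample's time; offset is the last sample's time + dt (half-open).
    """
    params = params or DetectionParams()
    params.validate()
    if stats.degenerate:
        raise ValueError("degenerate velocity statistics: session unusable "
                         "for detection")
    vx = np.asarray(vx, dtype=float)
    if time_ms is None:
        time_ms = np.arange(len(vx)) * dt_ms
    else:
        time_ms = np.asarray(time_ms, dtype=float)
        if len(time_ms) >= 2:
            dt_ms = float(time_ms[1] - time_ms[0])

    if params.use_elliptic:
        if vy is None or not np.isfinite(stats.sigma_y):
            raise ValueError("elliptic criterion needs vy and sigma_y")
        sx = params.lambda_threshold * stats.sigma_x
        sy = params.lambda_threshold * stats.sigma_y
        with np.errstate(invalid="ignore"):
            above = (vx / sx) ** 2 + (np.asarray(vy, float) / sy) ** 2 > 1.0
    else:
        with np.errstate(invalid="ignore"):
            above = np.abs(vx) > params.lambda_threshold * stats.sigma_x
    above = np.where(np.isfinite(vx), above, False)

    min_samples = math.ceil(params.min_duration_ms / dt_ms)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    events = []
    for s, e in zip(edges[0::2], edges[1::2]):
        if e - s < min_samples:
            continue
        onset = float(time_ms[s])
        offset = float(time_ms[e - 1]) + dt_ms
        events.append(MicrosaccadeEvent(onset, offset, offset - onset))
    return events


def filter_events(candidates: list[MicrosaccadeEvent],
                  params: DetectionParams | None = None) -> list[MicrosaccadeEvent]:
    """Apply the duration (3-110 ms) and minimum-interval (20 ms) rules.

    Single left-to-right pass; the interval is measured to the previous
    KEPT event (offset-to-onset by default), keeping the earlier event on
    conflict.  Idempotent; output is a subset of the input.
    """
    params = params or DetectionParams()
    params.validate()
    onsets = [c.onset_ms for c in candidates]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("candidates must be sorted by onset")
    kept: list[MicrosaccadeEvent] = []
    for c in candidates:
        if c.duration_ms < params.min_duration_ms:
            continue
        if c.duration_ms > params.max_duration_ms:
            continue
        if kept:
            prev = kept[-1]
            ref = (prev.offset_ms if params.interval_rule == "offset_to_onset"
                   else prev.onset_ms)
            if c.onset_ms - ref < params.min_interval_ms:
                continue
        kept.append(c)
    return kept


def event_properties(recording: GazeRecording, event: MicrosaccadeEvent,
                     vx: np.ndarray, vy: np.ndarray) -> MicrosaccadeEvent:
    """Amplitude and peak velocity of one event.

    Amplitude: Euclidean distance between the mean gaze position of the two
    samples before onset and the two samples after offset.  Peak velocity:
    maximum 2-D velocity magnitude inside the event.  Events at the trace
    edge are flagged and computed from the available samples.
    """
    t = recording.time_ms
    i0 = int(np.searchsorted(t, event.onset_ms - 1e-9))
    i1 = int(np.searchsorted(t, event.offset_ms - 1e-9))  # one past last sample
    pre = slice(max(i0 - 2, 0), i0)
    post = slice(i1, min(i1 + 2, recording.n_samples))
    at_edge = (i0 - 2 < 0) or (i1 + 2 > recording.n_samples)
    if pre.stop <= pre.start or post.stop <= post.start:
        # no samples on one side: fall back to the event's own endpoints
        pre = slice(i0, i0 + 1)
        post = slice(max(i1 - 1, i0), i1)
        at_edge = True
    dx = np.mean(recording.x_deg[post]) - np.mean(recording.x_deg[pre])
    dy = np.mean(recording.y_deg[post]) - np.mean(recording.y_deg[pre])
    speed = np.hypot(vx[i0:i1], vy[i0:i1])
    peak = float(np.nanmax(speed)) if i1 > i0 else np.nan
    event.amplitude_deg = float(np.hypot(dx, dy))
    event.peak_velocity_deg_s = peak
    event.at_edge = at_edge
    return event


def detect_microsaccades(recording: GazeRecording, stats: VelocityStats,
                         params: DetectionParams | None = None,
                         ) -> list[MicrosaccadeEvent]:
    """Full per-trial detection given precomputed session statistics."""
    params = params or DetectionParams()
    vx, vy = compute_velocity(recording)
    cands = detect_candidates(vx, stats, params, time_ms=recording.time_ms,
                              dt_ms=recording.dt_ms, vy=vy)
    events = filter_events(cands, params)
    for ev in events:
        event_properties(recording, ev, vx, vy)
        ev.trial_id = recording.trial_id
        ev.session_id = recording.session_id
    return events


def main_sequence(events) -> tuple[float, int]:
    """Pearson correlation of amplitude vs peak velocity over an event set."""
    amps = np.array([e.amplitude_deg for e in events], dtype=float)
    vels = np.array([e.peak_velocity_deg_s for e in events], dtype=float)
    ok = np.isfinite(amps) & np.isfinite(vels)
    amps, vels = amps[ok], vels[ok]
    if len(amps) < 3:
        raise ValueError("need at least 3 events")
    if np.std(amps) == 0 or np.std(vels) == 0:
        raise ValueError("zero variance in amplitude or peak velocity")
    r = float(np.corrcoef(amps, vels)[0, 1])
    return r, len(amps)


def events_to_frame(events) -> pd.DataFrame:
    """Serialize events in the CSV column layout used by the pipeline."""
    return pd.DataFrame([{
        "session_id": e.session_id,
        "trial_id": e.trial_id,
        "onset_ms": e.onset_ms,
        "offset_ms": e.offset_ms,
        "duration_ms": e.duration_ms,
        "amplitude_deg": e.amplitude_deg,
        "peak_velocity_deg_s": e.peak_velocity_deg_s,
    } for e in events])
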