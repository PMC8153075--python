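"""Tabular gaze-sample I/O, blink detection, and per-trial gaze durations.

The sample dialect is a tab-separated text file standing in for an ASCII
eye-tracker export: ``#``-prefixed header lines declare identifiers,
sampling rate and column order, then one row per sample.  Missing pupil
samples are serialized as ``NA``.  Positions are written at full float
precision (``%.17g``) so that write -> read is an exact inverse; times are
written with one decimal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .design import TrialSpec, FRAME_DURATION_MS


@dataclass
class GazeRecording:
    """One trial's eye-tracker sample stream.

    ``time_ms`` must be strictly increasing with a constant step of
    ``1000 / sampling_rate_hz`` ms.  ``pupil`` uses NaN for missing (blink)
    samples.
    """

    time_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    pupil: np.ndarray
    sampling_rate_hz: float = 500.0
    session_id: str = ""
    trial_id: int = -1
    #: free-form side channel (e.g. generator ground truth); not serialized
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        n = len(self.time_ms)
        if not (len(self.x_deg) == len(self.y_deg) == len(self.pupil) == n):
            raise ValueError("all channels must have equal length")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return len(self.time_ms)

    def validate(self) -> None:
        if self.n_samples >= 2:
            steps = np.diff(self.time_ms)
            if np.any(steps <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(steps, self.dt_ms, atol=1e-6):
                raise ValueError("timestamps must advance by the sample period")
        if not np.all(np.isfinite(self.x_deg)) or not np.all(np.isfinite(self.y_deg)):
            raise ValueError("gaze positions must be finite")


@dataclass(frozen=True, order=True)
class BlinkInterval:
    """Half-open [start, end) interval of missing pupil data, in ms."""
    start_ms: float
    end_ms: float

    def __post_init__(self):
        if self.end_ms <= self.start_ms:
            raise ValueError("end must be > start")


@dataclass
class GazeDurationRecord:
    trial_id: int
    gaze_start_ms: float = np.nan
    gaze_end_ms: float = np.nan
    duration_ms: float = np.nan
    valid: bool = False
    exclusion_reason: str = "none"  # none | response_during_gaze | no_spanning_fixation


_COLUMNS = ("time_ms", "x_deg", "y_deg", "pupil_au")


def write_samples(recording: GazeRecording, path) -> None:
    """Serialize a recording to the tab-separated sample dialect."""
    recording.validate()
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# session_id: {recording.session_id}\n")
        fh.write(f"# trial_id: {recording.trial_id}\n")
        fh.write(f"# sampling_rate_hz: {recording.sampling_rate_hz:.17g}\n")
        fh.write("# columns: " + "\t".join(_COLUMNS) + "\n")
        for t, x, y, p in zip(recording.time_ms, recording.x_deg,
                              recording.y_deg, recording.pupil):
            ps = "NA" if np.isnan(p) else f"{p:.17g}"
            fh.write(f"{t:.1f}\t{x:.17g}\t{y:.17g}\t{ps}\n")


def read_samples(path) -> GazeRecording:
    """Parse a sample file; raises ValueError with the offending line number
    on malformed rows or non-monotone timestamps."""
    header: dict[str, str] = {}
    times, xs, ys, ps = [], [], [], []
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    header[k.strip()] = v.strip()
                continue
            parts = line.split("\t")
            if n_cols is None:
                n_cols = len(parts)
                if n_cols not in (3, 4):
                    raise ValueError(f"line {lineno}: expected 3 or 4 columns, "
                                     f"got {n_cols}")
                if n_cols == 3:
                    warnings.warn(f"{path}: no pupil column; pupil set to "
                                  "all-missing", stacklevel=2)
            elif len(parts) != n_cols:
                raise ValueError(f"line {lineno}: expected {n_cols} columns, "
                                 f"got {len(parts)}")
            try:
                t = float(parts[0])
                x = float(parts[1])
                y = float(parts[2])
                p = np.nan
                if n_cols == 4:
                    p = np.nan if parts[3] == "NA" else float(parts[3])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed row: {exc}") from None
            if times and t <= times[-1]:
                raise ValueError(f"line {lineno}: non-monotone timestamp "
                                 f"{t} after {times[-1]}")
            times.append(t); xs.append(x); ys.append(y); ps.append(p)

    if "sampling_rate_hz" not in header:
        raise ValueError("header does not declare sampling_rate_hz")
    rec = GazeRecording(
        time_ms=np.array(times), x_deg=np.array(xs), y_deg=np.array(ys),
        pupil=np.array(ps),
        sampling_rate_hz=float(header["sampling_rate_hz"]),
        session_id=header.get("session_id", ""),
        trial_id=int(header.get("trial_id", -1)),
    )
    rec.validate()
    return rec


def detect_blinks(recording: GazeRecording, min_gap_ms: float = 0.0,
                  pad_ms: float = 50.0) -> list[BlinkInterval]:
    """Find blink intervals as maximal runs of missing (NaN) or non-positive
    pupil samples, padded by ``pad_ms`` on both sides; padded intervals that
    overlap, or whose gap is below ``min_gap_ms``, are merged."""
    p = recording.pupil
    bad = ~np.isfinite(p) | (p <= 0)
    if not bad.any():
        return []
    dt = recording.dt_ms
    t0 = recording.time_ms[0]
    edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
    starts, ends = edges[0::2], edges[1::2]
    intervals = []
    for s, e in zip(starts, ends):
        start = t0 + s * dt - pad_ms
        end = t0 + e * dt + pad_ms
        if intervals and start - intervals[-1][1] < max(min_gap_ms, 0.0):
            intervals[-1][1] = max(intervals[-1][1], end)
        else:
            intervals.append([start, end])
    return [BlinkInterval(s, e) for s, e in intervals]


def _disruption_intervals(saccade_events, blink_intervals) -> list[tuple[float, float]]:
    """Merge saccade extents and blink intervals into sorted disjoint spans."""
    spans = []
    for ev in saccade_events:
        spans.append((float(ev.onset_ms), float(ev.offset_ms)))
    for b in blink_intervals:
        spans.append((float(b.start_ms), float(b.end_ms)))
    spans.sort()
    merged: list[list[float]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def extract_gaze_duration(recording: GazeRecording, trial: TrialSpec,
                          saccade_events, blink_intervals,
                          response_time_ms: float | None = None,
                          ) -> GazeDurationRecord:
    """Identify the single fixation ("gaze") spanning the whole Ternus
    presentation and return its duration.

    The gaze is the maximal interval free of saccades and blinks that
    contains [frame1 onset, frame2 offset); on frame-less (E4) trials the
    beep anchors span the same window.  Trials where no fixation spans the
    presentation, or where the response falls inside the gaze, are flagged
    invalid.
    """
    win_start = trial.anchor("frame1")
    win_end = trial.anchor("frame2") + FRAME_DURATION_MS
    rec_start, rec_end = recording.time_ms[0], recording.time_ms[-1] + recording.dt_ms

    gaze_start, gaze_end = rec_start, rec_end
    for s, e in _disruption_intervals(saccade_events, blink_intervals):
        if e <= win_start:
            gaze_start = max(gaze_start, e)
        elif s >= win_end:
            gaze_end = min(gaze_end, s)
        else:  # disruption overlaps the presentation window
            return GazeDurationRecord(trial.trial_id,
                                      exclusion_reason="no_spanning_fixation")
    if gaze_start > win_start or gaze_end < win_end:
        return GazeDurationRecord(trial.trial_id,
                                  exclusion_reason="no_spanning_fixation")
    rec = GazeDurationRecord(trial.trial_id, gaze_start, gaze_end,
                             gaze_end - gaze_start, valid=True)
    if response_time_ms is not None and gaze_start <= response_time_ms < gaze_end:
        rec.valid = False
        rec.exclusion_reason = "response_during_gaze"
        rec.duration_ms = np.nan
    return rec
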