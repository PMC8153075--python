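"""Pupillometry preprocessing and condition averages.

Order of operations mirrors standard pupillometry practice: blink samples
are linearly interpolated, the whole session is z-scored (mean/SD over all
interpolated samples), epochs are cut relative to the first Ternus frame
(or first beep) and baseline-corrected by the mean over [-100, 0) ms, and
condition averages are two-level (trials -> participant -> grand mean),
with the standard error taken across participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gaze_io import GazeRecording, BlinkInterval


@dataclass
class PupilEpoch:
    time_ms: np.ndarray           # relative to the lock event
    values: np.ndarray            # z-units, baseline-corrected
    trial_id: int = -1
    condition: dict = field(default_factory=dict)


def interpolate_blinks(trace: np.ndarray,
                       blink_intervals: list[BlinkInterval] | None = None,
                       time_ms: np.ndarray | None = None) -> np.ndarray:
    """Replace blink samples by linear interpolation between the nearest
    valid neighbours; leading/trailing gaps are filled with the nearest
    valid value.  Valid samples are never modified.

    When ``blink_intervals`` is None, every non-finite sample is treated as
    blink.
    """
    v = np.asarray(trace, dtype=float).copy()
    n = len(v)
    if time_ms is None:
        time_ms = np.arange(n, dtype=float)
    bad = ~np.isfinite(v)
    if blink_intervals is not None:
        for b in blink_intervals:
            bad |= (time_ms >= b.start_ms) & (time_ms < b.end_ms)
    if not bad.any():
        return v
    if bad.all():
        raise ValueError("trace entirely missing")
    good = ~bad
    v[bad] = np.interp(time_ms[bad], time_ms[good], v[good])
    return v


def normalize_session(samples: np.ndarray) -> tuple[np.ndarray, float, float]:
    """z-score over all (interpolated) samples of a session.

    Returns (z, mean, sd).  A zero-variance session raises: the pupil
    channel is constant or invalid.
    """
    p = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("normalize_session expects interpolated (finite) data")
    mean = float(p.mean())
    sd = float(p.std(ddof=0))
    if sd == 0:
        raise ValueError("zero session variance: constant pupil channel")
    return (p - mean) / sd, mean, sd


def baseline_correct(epoch: PupilEpoch,
                     baseline_window_ms: tuple[float, float] = (-100.0, 0.0),
                     ) -> PupilEpoch:
    """Subtract the mean over the half-open baseline window from the epoch."""
    lo, hi = baseline_window_ms
    m = (epoch.time_ms >= lo) & (epoch.time_ms < hi)
    if not m.any():
        raise ValueError("epoch does not cover the baseline window")
    epoch.values = epoch.values - epoch.values[m].mean()
    return epoch


def epoch_average(epochs_by_participant: dict) -> tuple[np.ndarray, np.ndarray, int]:
    """Two-level average: trials -> participant mean -> grand mean.

    ``epochs_by_participant`` maps participant id -> 2-D array
    (trials x time).  Returns (grand_mean, se_across_participants,
    n_participants); the grand mean weighs every participant equally
    regardless of trial count.
    """
    if not epochs_by_participant:
        raise ValueError("no participants")
    means = []
    for pid, arr in epochs_by_participant.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        means.append(arr.mean(axis=0))
    means = np.vstack(means)
    grand = means.mean(axis=0)
    n = means.shape[0]
    se = means.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(grand)
    return grand, se, n
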