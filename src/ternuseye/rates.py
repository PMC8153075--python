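"""Time-locked, kernel-smoothed microsaccade rate curves.

Event onsets are binned into a trials x time raster relative to a lock
event (first/second Ternus frame or first beep); the raw rate is the
trial-mean times the sampling rate (events/s), causally smoothed with the
kernel omega(tau) = alpha^2 * tau * exp(-alpha*tau) (alpha = 1/20 per ms),
discretized, truncated and renormalized to unit sum so that total event
mass is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SEGMENT_BOUNDARIES_MS = (0.0, 250.0, 500.0, 750.0, 1000.0)
SEGMENT_LABELS = ("S1", "S2", "S3", "S4")


@dataclass
class KernelSpec:
    alpha_per_ms: float = 1.0 / 20.0
    support_ms: float = 200.0
    step_ms: float = 2.0

    def validate(self) -> None:
        if self.alpha_per_ms <= 0:
            raise ValueError("alpha must be > 0")
        if self.support_ms < 5.0 / self.alpha_per_ms:
            raise ValueError("kernel support shorter than 5 time constants")


@dataclass
class RateCurve:
    time_ms: np.ndarray
    rate_hz: np.ndarray
    n_trials: int
    lock: str = "frame1"
    condition: dict = field(default_factory=dict)


@dataclass
class SegmentScheme:
    boundaries_ms: tuple = SEGMENT_BOUNDARIES_MS
    labels: tuple = SEGMENT_LABELS

    def validate(self) -> None:
        b = np.asarray(self.boundaries_ms, dtype=float)
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.labels) != len(b) - 1:
            raise ValueError("need one label per bin")


def event_raster(onsets_by_trial: dict, lock_times: dict,
                 window_ms: tuple[float, float] = (-500.0, 1000.0),
                 dt_ms: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Binary onset raster, trials x time bins.

    Parameters
    ----------
    onsets_by_trial
        trial_id -> sequence of event onset times (ms, same clock as the
        lock times).
    lock_times
        trial_id -> lock event onset (ms).  Every trial in
        ``onsets_by_trial`` must be present; a missing lock raises KeyError.
    window_ms
        Half-open window [start, end) relative to the lock event.

    Returns (raster, time_grid) where time_grid holds each bin's left edge.
    """
    w0, w1 = window_ms
    n_bins = int(round((w1 - w0) / dt_ms))
    grid = w0 + np.arange(n_bins) * dt_ms
    trial_ids = list(onsets_by_trial)
    raster = np.zeros((len(trial_ids), n_bins), dtype=float)
    for i, tid in enumerate(trial_ids):
        if tid not in lock_times:
            raise KeyError(f"trial {tid} has no lock event time")
        t0 = lock_times[tid]
        for onset in onsets_by_trial[tid]:
            k = int(np.floor((onset - t0 - w0) / dt_ms))
            if 0 <= k < n_bins:
                raster[i, k] = 1.0
    return raster, grid


def smoothing_kernel(spec: KernelSpec | None = None) -> np.ndarray:
    """Discrete causal kernel: omega[k] ~ alpha^2*(k*dt)*exp(-alpha*k*dt),
    k >= 0, truncated at ``support_ms`` and renormalized to sum one.
    omega[0] = 0, and the peak sits at tau = 1/alpha (nearest grid point)."""
    spec = spec or KernelSpec()
    spec.validate()
    k = np.arange(int(round(spec.support_ms / spec.step_ms)) + 1)
    tau = k * spec.step_ms
    w = spec.alpha_per_ms ** 2 * tau * np.exp(-spec.alpha_per_ms * tau)
    return w / w.sum()


def rate_curve(raster: np.ndarray, sampling_rate_hz: float = 500.0,
               kernel: np.ndarray | None = None,
               time_ms: np.ndarray | None = None,
               lock: str = "frame1", condition: dict | None = None) -> RateCurve:
    """Trial-normalized, kernel-smoothed event rate in events/s.

    The raw rate is (sum over trials)/n_trials * sampling_rate; causal
    convolution treats rate outside the window as zero, so mass within the
    window is conserved up to edge truncation.
    """
    raster = np.atleast_2d(np.asarray(raster, dtype=float))
    n_trials = raster.shape[0]
    if n_trials == 0 or raster.size == 0:
        raise ValueError("raster must contain at least one trial")
    if kernel is None:
        kernel = smoothing_kernel(KernelSpec(step_ms=1000.0 / sampling_rate_hz))
    raw = raster.mean(axis=0) * sampling_rate_hz
    smoothed = np.convolve(raw, kernel)[: raw.size]
    if time_ms is None:
        time_ms = np.arange(raw.size) * 1000.0 / sampling_rate_hz
    return RateCurve(np.asarray(time_ms, dtype=float), smoothed, n_trials,
                     lock=lock, condition=dict(condition or {}))


def smooth_rows(raster: np.ndarray, sampling_rate_hz: float,
                kernel: np.ndarray) -> np.ndarray:
    """Row-wise smoothed rates (per-trial or per-participant curves)."""
    raster = np.atleast_2d(np.asarray(raster, dtype=float))
    rate = raster * sampling_rate_hz
    out = np.empty_like(rate)
    for i in range(rate.shape[0]):
        out[i] = np.convolve(rate[i], kernel)[: rate.shape[1]]
    return out


def bin_segments(curve: RateCurve, scheme: SegmentScheme | None = None) -> dict:
    """Mean rate within each half-open segment [b_i, b_{i+1})."""
    scheme = scheme or SegmentScheme()
    scheme.validate()
    b = np.asarray(scheme.boundaries_ms, dtype=float)
    t = curve.time_ms
    if t[0] > b[0] or t[-1] + (t[1] - t[0]) < b[-1]:
        raise ValueError("curve window does not cover the segment scheme")
    out = {}
    for lab, lo, hi in zip(scheme.labels, b[:-1], b[1:]):
        m = (t >= lo) & (t < hi)
        out[lab] = float(curve.rate_hz[m].mean())
    return out
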