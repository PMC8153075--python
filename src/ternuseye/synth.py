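"""Synthetic behavioral and eye-tracking data for the Ternus experiments.

Behavioral responses are Bernoulli draws from the observer's true logistic
psychometric function (E1-E3) or truncated-normal reaction times (E4).
Gaze traces are fixational drift (Ornstein-Uhlenbeck velocity) plus
microsaccade waveforms from an inhomogeneous point process whose rate is
the base rate modulated by stimulus-locked inhibition and rebound; sound
deepens and prolongs the late (response-phase) inhibition.  Each
microsaccade is a smooth minimum-jerk displacement ramp whose amplitude is
lognormal and whose peak velocity follows the main sequence (slope x
amplitude x lognormal noise).  Pupil traces are a session baseline plus
gamma-shaped impulse responses per stimulus event (beeps add extra gain),
Gaussian noise, and Poisson blinks.

All generation is a pure function of (params, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as ssig
from scipy import stats as sps

from .design import ExperimentDesign, TrialSpec, FRAME_DURATION_MS, build_design
from .gaze_io import GazeRecording, write_samples
from .psychometrics import LN3

_MINJERK_PEAK = 1.875  # peak velocity of a minimum-jerk ramp: 15/8 * A / D


def _truncnorm(rng, mean, sd, lower, size=None):
    a = (lower - mean) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                             random_state=rng)


def sample_behavior(design: ExperimentDesign, params, seed) -> pd.DataFrame:
    """Per-trial responses.

    E1-E3: ``group_motion`` ~ Bernoulli(logistic((SOA - PSE_cond)/s_cond))
    with s_cond = JND_cond / ln 3.  E4: ``rt_ms`` from a truncated normal
    with condition-specific mean.  ``response_time_ms`` is the absolute
    response timestamp (probe onset + reaction time), used downstream for
    the gaze-duration exclusion rule.
    """
    params.validate()
    psy = params.psychometric
    rng = np.random.default_rng(seed)
    rows = []
    for t in design.trials:
        probe = t.timeline["probe"]
        row = {"trial_id": t.trial_id, "soa_ms": t.soa_ms, "sound": t.sound,
               "direction": t.direction}
        if design.experiment_id == "E4":
            mean = params.rt.mean_sound_ms if t.sound else params.rt.mean_baseline_ms
            rt = float(_truncnorm(rng, mean, params.rt.sd_ms,
                                  params.rt.lower_bound_ms))
            row["rt_ms"] = rt
            row["response_time_ms"] = probe + rt
        else:
            pse = psy.pse_sound_ms if t.sound else psy.pse_baseline_ms
            jnd = psy.jnd_sound_ms if t.sound else psy.jnd_baseline_ms
            s = jnd / LN3
            p = 1.0 / (1.0 + np.exp(-(t.soa_ms - pse) / s))
            row["group_motion"] = bool(rng.random() < p)
            rt = float(_truncnorm(rng, 600.0, 150.0, 150.0))
            row["response_time_ms"] = probe + rt
        rows.append(row)
    return pd.DataFrame(rows)


def rate_gain(t_ms: np.ndarray, trial: TrialSpec, ms) -> np.ndarray:
    """Multiplicative modulation of the microsaccade rate around the
    stimulus events.  ``t_ms`` is absolute trial time."""
    f1 = trial.anchor("frame1")
    try:
        f2 = trial.anchor("frame2")
    except KeyError:
        f2 = f1 + trial.soa_ms
    g = np.ones_like(t_ms, dtype=float)
    for tf in (f1, f2):
        g *= 1.0 - ms.inhib_depth * np.exp(
            -0.5 * ((t_ms - tf - ms.inhib_latency_ms) / ms.inhib_width_ms) ** 2)
    g *= 1.0 + ms.rebound_gain * np.exp(
        -0.5 * ((t_ms - f2 - ms.rebound_latency_ms) / ms.rebound_width_ms) ** 2)
    if trial.sound:
        g *= 1.0 - ms.sound_late_depth * np.exp(
            -0.5 * ((t_ms - f1 - ms.sound_late_center_ms)
                    / ms.sound_late_width_ms) ** 2)
    return np.clip(g, 0.0, None)


def _minimum_jerk(n: int) -> np.ndarray:
    """Unit displacement ramp s(u) = 10u^3 - 15u^4 + 6u^5 on n samples."""
    u = np.linspace(0.0, 1.0, n)
    return 10 * u ** 3 - 15 * u ** 4 + 6 * u ** 5


def simulate_gaze_trial(trial: TrialSpec, params, seed,
                        window_ms: tuple[float, float] = (-1200.0, 1600.0),
                        ) -> GazeRecording:
    """Simulate one trial's 500-Hz gaze trace around frame1.

    ``window_ms`` is relative to the frame1 anchor and must cover at least
    [-500, +1500] ms.  The injected ground-truth events are stored in
    ``recording.meta["injected_events"]``.
    """
    params.validate()
    ms = params.ms_process
    pre, post = window_ms
    if pre > -500.0 or post < 1500.0:
        raise ValueError("window must cover at least [-500, +1500] ms "
                         "around frame1")
    dt = 1000.0 / params.sampling_rate_hz
    span = post - pre
    n = span / dt
    if abs(n - round(n)) > 1e-9:
        raise ValueError("window length must be divisible by the sample period")
    n = int(round(n))
    rng = np.random.default_rng(seed)
    anchor = trial.anchor("frame1")
    time_ms = anchor + pre + np.arange(n) * dt

    # fixational drift: Ornstein-Uhlenbeck velocity, integrated to position
    dt_s = dt / 1000.0
    tau_s = ms.drift_timescale_ms / 1000.0
    a = 1.0 - dt_s / tau_s
    innov_sd = ms.drift_velocity_sd * np.sqrt(2.0 * dt_s / tau_s)
    x = np.zeros(n)
    y = np.zeros(n)
    for arr in (x, y):
        v = ssig.lfilter([innov_sd], [1.0, -a], rng.standard_normal(n))
        arr += np.cumsum(v) * dt_s

    # inhomogeneous point process by thinning, then waveform injection
    lam_max = ms.base_rate_hz * (1.0 + ms.rebound_gain)
    events = []
    if lam_max > 0:
        n_cand = rng.poisson(lam_max * span / 1000.0)
        cand = np.sort(rng.uniform(time_ms[0], time_ms[-1], size=n_cand))
        accept_u = rng.random(n_cand)
        gains = rate_gain(cand, trial, ms) * ms.base_rate_hz / lam_max
        cand = cand[accept_u < gains]
        margin = 6 * dt
        last_offset = -np.inf
        for onset in cand:
            amp = float(np.clip(
                ms.amplitude_median_deg * rng.lognormal(0.0, ms.amplitude_sigma),
                ms.amplitude_min_deg, ms.amplitude_max_deg))
            noise = rng.lognormal(0.0, ms.main_sequence_noise_sigma)
            dur = _MINJERK_PEAK / (ms.main_sequence_slope * noise) * 1000.0
            dur = float(np.clip(np.round(dur / dt) * dt, 4 * dt, 60.0))
            if onset - last_offset < ms.min_gap_ms:
                continue
            if onset < time_ms[0] + margin or onset + dur > time_ms[-1] - margin:
                continue
            # snap the bookkept onset to the sample where the ramp starts
            onset = float(time_ms[int(np.round((onset - time_ms[0]) / dt))])
            events.append({"onset_ms": float(onset), "duration_ms": dur,
                           "amplitude_deg": amp,
                           "peak_velocity_deg_s": _MINJERK_PEAK * amp / (dur / 1000.0)})
            last_offset = onset + dur

        for ev in events:
            i0 = int(np.round((ev["onset_ms"] - time_ms[0]) / dt))
            n_samp = int(round(ev["duration_ms"] / dt)) + 1
            ramp = _minimum_jerk(n_samp) * ev["amplitude_deg"]
            # direction: horizontally biased, drawn toward the fixation point
            ang = np.deg2rad(rng.normal(0.0, 15.0))
            toward_center = -np.sign(x[i0]) if abs(x[i0]) > 0.2 else \
                (1.0 if rng.random() < 0.5 else -1.0)
            dx = toward_center * np.cos(ang)
            dy = np.sin(ang)
            ev["direction_x"] = float(dx)
            x[i0:i0 + n_samp] += dx * ramp
            x[i0 + n_samp:] += dx * ramp[-1]
            y[i0:i0 + n_samp] += dy * ramp
            y[i0 + n_samp:] += dy * ramp[-1]

    if ms.position_noise_sd_deg > 0:
        x = x + rng.normal(0.0, ms.position_noise_sd_deg, n)
        y = y + rng.normal(0.0, ms.position_noise_sd_deg, n)

    rec = GazeRecording(time_ms=time_ms, x_deg=x, y_deg=y,
                        pupil=np.full(n, np.nan),
                        sampling_rate_hz=params.sampling_rate_hz,
                        trial_id=trial.trial_id,
                        meta={"injected_events": events})
    return rec


def pupil_impulse_response(t_ms: np.ndarray, time_to_peak_ms: float,
                           shape_n: float) -> np.ndarray:
    """Gamma-shaped impulse response, unit peak at ``time_to_peak_ms``:
    h(t) = (t/tp)^n * exp(n * (1 - t/tp)) for t > 0, else 0."""
    t = np.asarray(t_ms, dtype=float)
    h = np.zeros_like(t)
    pos = t > 0
    u = t[pos] / time_to_peak_ms
    h[pos] = u ** shape_n * np.exp(shape_n * (1.0 - u))
    return h


def simulate_pupil_trial(trial: TrialSpec, recording: GazeRecording,
                         params, seed) -> GazeRecording:
    """Fill the recording's pupil channel in place.

    Pupil = session baseline + impulse responses per stimulus event (visual
    frames; beeps add ``sound_gain_au`` when sound is present) + Gaussian
    noise; Poisson blink intervals are set to missing (NaN).
    """
    params.validate()
    pp = params.pupil
    rng = np.random.default_rng(seed)
    t = recording.time_ms
    p = np.full(recording.n_samples, pp.baseline_au, dtype=float)

    visual = [trial.timeline[k] for k in ("frame1", "frame2")
              if k in trial.timeline]
    beeps = [trial.timeline[k] for k in ("beep1", "beep2")
             if k in trial.timeline] if trial.sound else []
    for ev in visual:
        p += pp.response_gain_au * pupil_impulse_response(
            t - ev, pp.time_to_peak_ms, pp.shape_n)
    for ev in beeps:
        p += pp.sound_gain_au * pupil_impulse_response(
            t - ev, pp.time_to_peak_ms, pp.shape_n)
    if pp.noise_sd_au > 0:
        p += rng.normal(0.0, pp.noise_sd_au, recording.n_samples)

    span_s = (t[-1] - t[0]) / 1000.0
    n_blinks = rng.poisson(pp.blink_rate_hz * span_s)
    blinks = []
    for _ in range(n_blinks):
        start = rng.uniform(t[0], t[-1])
        dur = max(float(rng.normal(pp.blink_duration_ms,
                                   pp.blink_duration_ms / 4.0)), 40.0)
        p[(t >= start) & (t < start + dur)] = np.nan
        blinks.append((start, start + dur))
    recording.pupil = p
    recording.meta["injected_blinks"] = blinks
    return recording


def simulate_session(design: ExperimentDesign, params, seed,
                     session_id: str = "",
                     window_ms: tuple[float, float] = (-1200.0, 1600.0),
                     with_pupil: bool = True):
    """Simulate one participant's full session.

    Returns (recordings, responses); per-trial randomness is spawned from
    ``seed`` so the session is a pure function of (design, params, seed).
    """
    ss = np.random.SeedSequence(seed)
    beh_seed, *trial_seeds = ss.spawn(1 + len(design.trials))
    responses = sample_behavior(design, params, beh_seed)
    recordings = []
    for trial, tseed in zip(design.trials, trial_seeds):
        child = tseed.generate_state(2)
        rec = simulate_gaze_trial(trial, params, child[0], window_ms)
        if with_pupil:
            simulate_pupil_trial(trial, rec, params, child[1])
        rec.session_id = session_id
        recordings.append(rec)
    return recordings, responses


def simulate_null_rate_curves(n_participants: int = 17, n_trials: int = 60,
                              base_rate_hz: float = 1.5,
                              window_ms: tuple[float, float] = (-500.0, 1000.0),
                              dt_ms: float = 2.0, seed=None,
                              kernel: np.ndarray | None = None):
    """Per-participant kernel-smoothed rate curves from a homogeneous
    Bernoulli onset process — the sign-symmetric null used to probe the
    familywise error rate of the cluster test.

    Returns (curves, grid): curves is participants x time (events/s).
    """
    from . import rates
    rng = np.random.default_rng(seed)
    if kernel is None:
        kernel = rates.smoothing_kernel(rates.KernelSpec(step_ms=dt_ms))
    n_bins = int(round((window_ms[1] - window_ms[0]) / dt_ms))
    grid = window_ms[0] + np.arange(n_bins) * dt_ms
    p = base_rate_hz * dt_ms / 1000.0
    sr = 1000.0 / dt_ms
    curves = np.empty((n_participants, n_bins))
    for i in range(n_participants):
        raster = (rng.random((n_trials, n_bins)) < p).astype(float)
        curves[i] = rates.rate_curve(raster, sr, kernel, time_ms=grid).rate_hz
    return curves, grid


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def generate_dataset(params, experiments, n_subjects: int, out_dir,
                     seed: int | None = None,
                     trials_per_cell: int | None = None) -> dict:
    """Write a complete synthetic dataset plus a manifest.

    Layout: ``<out>/<subject>_<experiment>/{trials.csv, responses.csv,
    samples/trial####.tsv}`` and ``<out>/manifest.json`` holding the seeds,
    a parameter snapshot and per-file checksums — enough to regenerate the
    dataset byte-identically.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    params.validate()
    if seed is None:
        seed = params.seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for exp in experiments:
        for si in range(n_subjects):
            sub = f"sub{si + 1:02d}_{exp}"
            sdir = out / sub
            (sdir / "samples").mkdir(parents=True, exist_ok=True)
            design_seed = int(np.random.SeedSequence(
                [seed, experiments.index(exp), si]).generate_state(1)[0] % (2 ** 31))
            design = build_design(exp, design_seed)
            if trials_per_cell:
                from .design import subset_per_cell
                design = subset_per_cell(design, trials_per_cell)
            recs, responses = simulate_session(
                design, params, [seed, experiments.index(exp), si, 1],
                session_id=sub)
            design.to_frame().to_csv(sdir / "trials.csv", index=False)
            responses.to_csv(sdir / "responses.csv", index=False)
            for rec in recs:
                fp = sdir / "samples" / f"trial{rec.trial_id:04d}.tsv"
                write_samples(rec, fp)
            for fp in sorted(sdir.rglob("*")):
                if fp.is_file():
                    files[str(fp.relative_to(out))] = _sha256(fp)
    manifest = {
        "seed": int(seed),
        "experiments": list(experiments),
        "n_subjects": int(n_subjects),
        "trials_per_cell": trials_per_cell,
        "params": params.to_dict(),
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def regenerate_from_manifest(manifest: dict, out_dir) -> dict:
    """Re-run ``generate_dataset`` from a manifest's seeds and parameters."""
    from .params import GeneratorParams
    params = GeneratorParams.from_dict(manifest["params"])
    return generate_dataset(params, manifest["experiments"],
                            manifest["n_subjects"], out_dir,
                            seed=manifest["seed"],
                            trials_per_cell=manifest.get("trials_per_cell"))
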