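"""End-to-end pipeline: simulate/load -> detect -> rates -> pupil ->
psychometrics -> cluster statistics -> report.

Each stage writes a machine-readable artifact (CSV/JSON) when an output
directory is configured, and the report embeds the config snapshot and
seeds, so a rerun with identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detect as det
from . import cluster as cl
from . import pupil as pup
from . import psychometrics as psy
from . import rates
from .design import build_design, subset_per_cell
from .gaze_io import detect_blinks, extract_gaze_duration, read_samples
from .params import GeneratorParams
from .synth import simulate_session


class PipelineError(RuntimeError):
    """Raised with the stage name and offending session/trial context."""


@dataclass
class PipelineConfig:
    experiments: list = field(default_factory=lambda: ["E1"])
    n_subjects: int = 6
    trials_per_cell: int | None = None      # subsample each SOA x sound cell
    seed: int = 0
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    detection: det.DetectionParams = field(default_factory=det.DetectionParams)
    kernel: rates.KernelSpec = field(default_factory=rates.KernelSpec)
    window_ms: tuple = (-500.0, 1000.0)      # epoch window around the lock
    stats_window_ms: tuple = (0.0, 1000.0)   # cluster-test window
    baseline_window_ms: tuple = (-100.0, 0.0)
    locks: tuple = ("frame1", "frame2")
    n_iterations: int = 1000
    alpha: float = 0.05
    blink_pad_ms: float = 50.0
    dataset_dir: str | None = None           # load instead of simulate
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("experiments", "n_subjects", "trials_per_cell", "seed",
                    "n_iterations", "alpha", "blink_pad_ms", "dataset_dir",
                    "out_dir"):
            if key in raw:
                setattr(cfg, key, raw[key])
        for key in ("window_ms", "stats_window_ms", "baseline_window_ms",
                    "locks"):
            if key in raw:
                setattr(cfg, key, tuple(raw[key]))
        if "generator" in raw:
            cfg.generator = GeneratorParams.from_dict(raw["generator"])
        if "detection" in raw:
            cfg.detection = det.DetectionParams(**raw["detection"])
        if "kernel" in raw:
            cfg.kernel = rates.KernelSpec(**raw["kernel"])
        return cfg

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # output location is not an analysis parameter
        return d


@dataclass
class SessionData:
    session_id: str
    experiment_id: str
    trials: list                    # TrialSpec
    responses: pd.DataFrame
    recordings: list                # GazeRecording, ordered like trials


@dataclass
class SessionResult:
    session_id: str
    experiment_id: str
    events: list
    gaze_durations: pd.DataFrame
    rate_curves: dict               # (lock, cond) -> np.ndarray
    pupil_curves: dict              # cond -> np.ndarray
    psychometric: dict              # cond -> PsychometricFit (E1-E3)
    group_motion: dict              # cond -> proportion (E1-E3)
    sigma_x: float


def simulate_dataset(config: PipelineConfig) -> list[SessionData]:
    sessions = []
    for exp in config.experiments:
        for si in range(config.n_subjects):
            sid = f"sub{si + 1:02d}_{exp}"
            dseed = int(np.random.SeedSequence(
                [config.seed, config.experiments.index(exp), si]
            ).generate_state(1)[0] % (2 ** 31))
            design = build_design(exp, dseed)
            if config.trials_per_cell:
                design = subset_per_cell(design, config.trials_per_cell)
            recs, responses = simulate_session(
                design, config.generator,
                [config.seed, config.experiments.index(exp), si, 1],
                session_id=sid)
            sessions.append(SessionData(sid, exp, design.trials, responses, recs))
    return sessions


def load_dataset(dataset_dir) -> list[SessionData]:
    """Read a dataset written by ``synth.generate_dataset``."""
    from .design import TrialSpec
    root = Path(dataset_dir)
    sessions = []
    for sdir in sorted(p for p in root.iterdir() if p.is_dir()):
        trials_df = pd.read_csv(sdir / "trials.csv")
        responses = pd.read_csv(sdir / "responses.csv")
        exp = sdir.name.split("_")[-1]
        trials = []
        for _, row in trials_df.iterrows():
            tl = {}
            for col in trials_df.columns:
                if col.endswith("_ms") and col not in ("soa_ms",):
                    v = row[col]
                    if pd.notna(v):
                        tl[col[:-3]] = float(v)
            trials.append(TrialSpec(int(row["trial_id"]), float(row["soa_ms"]),
                                    bool(row["sound"]), str(row["direction"]),
                                    int(row["block"]), tl))
        recs = [read_samples(fp) for fp in sorted((sdir / "samples").glob("*.tsv"))]
        by_id = {r.trial_id: r for r in recs}
        recs = [by_id[t.trial_id] for t in trials]
        sessions.append(SessionData(sdir.name, exp, trials, responses, recs))
    return sessions


def analyze_session(session: SessionData, config: PipelineConfig) -> SessionResult:
    """Per-session stages: velocity stats, detection, gaze durations,
    pupil preprocessing, rate curves, psychometrics."""
    params = config.detection
    vxs, vys = [], []
    for rec in session.recordings:
        vx, vy = det.compute_velocity(rec)
        vxs.append(vx)
        vys.append(vy)
    stats = det.session_stats(vxs, vys, params)
    if stats.degenerate:
        raise PipelineError(f"detect: session {session.session_id} has "
                            "degenerate velocity statistics")

    events = []
    candidates_by_trial = {}
    blinks_by_trial = {}
    onsets_by_trial = {}
    for trial, rec, vx, vy in zip(session.trials, session.recordings, vxs, vys):
        cands = det.detect_candidates(vx, stats, params, time_ms=rec.time_ms,
                                      dt_ms=rec.dt_ms, vy=vy)
        candidates_by_trial[trial.trial_id] = cands
        kept = det.filter_events(cands, params)
        for ev in kept:
            det.event_properties(rec, ev, vx, vy)
            ev.trial_id = trial.trial_id
            ev.session_id = session.session_id
        events.extend(kept)
        onsets_by_trial[trial.trial_id] = [e.onset_ms for e in kept]
        blinks_by_trial[trial.trial_id] = detect_blinks(rec, pad_ms=config.blink_pad_ms)

    # gaze durations: any supra-threshold excursion (pre-filter candidate)
    # or blink breaks the gaze
    resp_times = dict(zip(session.responses["trial_id"],
                          session.responses["response_time_ms"]))
    gaze = [extract_gaze_duration(rec, trial, candidates_by_trial[trial.trial_id],
                                  blinks_by_trial[trial.trial_id],
                                  resp_times.get(trial.trial_id))
            for trial, rec in zip(session.trials, session.recordings)]
    gaze_df = pd.DataFrame([dataclasses.asdict(g) for g in gaze])
    gaze_df["sound"] = [t.sound for t in session.trials]
    gaze_df["soa_ms"] = [t.soa_ms for t in session.trials]

    # rate curves per (lock, condition): smooth the participant-mean raster
    kernel = rates.smoothing_kernel(config.kernel)
    sr = session.recordings[0].sampling_rate_hz
    dt = 1000.0 / sr
    curves = {}
    for lock in config.locks:
        lock_times = {t.trial_id: t.anchor(lock) for t in session.trials}
        for cond, flag in (("sound", True), ("baseline", False)):
            tids = [t.trial_id for t in session.trials if t.sound == flag]
            if not tids:
                continue
            raster, grid = rates.event_raster(
                {tid: onsets_by_trial[tid] for tid in tids}, lock_times,
                config.window_ms, dt)
            curve = rates.rate_curve(raster, sr, kernel, time_ms=grid,
                                     lock=lock, condition={"sound": flag})
            curves[(lock, cond)] = curve.rate_hz

    # pupil: interpolate -> session z-score -> epoch -> baseline-correct
    pupil_curves = {}
    has_pupil = any(np.isfinite(rec.pupil).any() for rec in session.recordings)
    if has_pupil:
        interp = [pup.interpolate_blinks(rec.pupil, blinks_by_trial[t.trial_id],
                                         rec.time_ms)
                  for t, rec in zip(session.trials, session.recordings)]
        _, mean, sd = pup.normalize_session(np.concatenate(interp))
        w0, w1 = config.window_ms
        n_bins = int(round((w1 - w0) / dt))
        epoch_grid = w0 + np.arange(n_bins) * dt
        by_cond: dict = {"sound": [], "baseline": []}
        for trial, rec, tr in zip(session.trials, session.recordings, interp):
            z = (tr - mean) / sd
            t0 = trial.anchor("frame1")
            i0 = int(np.round((t0 + w0 - rec.time_ms[0]) / dt))
            if i0 < 0 or i0 + n_bins > rec.n_samples:
                raise PipelineError(f"pupil: trial {trial.trial_id} of "
                                    f"{session.session_id} does not cover "
                                    "the epoch window")
            ep = pup.PupilEpoch(epoch_grid, z[i0:i0 + n_bins].copy(),
                                trial.trial_id)
            pup.baseline_correct(ep, config.baseline_window_ms)
            by_cond["sound" if trial.sound else "baseline"].append(ep.values)
        for cond, eps in by_cond.items():
            if eps:
                pupil_curves[cond] = np.vstack(eps).mean(axis=0)

    # psychometrics (E1-E3)
    fits = {}
    props = {}
    if "group_motion" in session.responses.columns:
        df = session.responses
        for cond, flag in (("sound", True), ("baseline", False)):
            sub = df[df["sound"] == flag]
            if sub.empty:
                continue
            agg = sub.groupby("soa_ms")["group_motion"].agg(["sum", "count"])
            fits[cond] = psy.fit_logistic(agg.index.to_numpy(),
                                          agg["sum"].to_numpy(),
                                          agg["count"].to_numpy())
            props[cond] = float(sub["group_motion"].mean())

    return SessionResult(session.session_id, session.experiment_id, events,
                         gaze_df, curves, pupil_curves, fits, props,
                         sigma_x=stats.sigma_x)


@dataclass
class AnalysisReport:
    config: dict
    psychometrics: pd.DataFrame
    gaze_durations: pd.DataFrame
    main_sequence_r: float
    n_events: int
    cluster_results: dict          # name -> ClusterTestResult
    segment_means: pd.DataFrame
    delta_correlation: cl.CorrelationResult | None
    rate_grid_ms: np.ndarray
    rate_curves: dict              # (lock, cond) -> participants x time
    pupil_curves: dict             # cond -> participants x time

    def to_dict(self) -> dict:
        def clusters_out(res):
            return {
                "threshold_t": res.threshold,
                "n_iterations": res.n_iterations,
                "alpha": res.alpha,
                "clusters": [dataclasses.asdict(c) for c in res.clusters],
            }
        from . import __version__
        return {
            "version": __version__,
            "config": self.config,
            "n_events": self.n_events,
            "main_sequence_r": self.main_sequence_r,
            "psychometrics": self.psychometrics.to_dict(orient="records"),
            "segment_means": self.segment_means.to_dict(orient="records"),
            "clusters": {k: clusters_out(v) for k, v in
                         self.cluster_results.items()},
            "delta_correlation": (dataclasses.asdict(self.delta_correlation)
                                  if self.delta_correlation else None),
        }


def group_analysis(results: list[SessionResult],
                   config: PipelineConfig) -> AnalysisReport:
    """Across-participant statistics: cluster-based permutation tests on the
    rate and pupil curves, segment means, psychometric table, and the
    delta-OMI vs delta-behavior correlation."""
    dt = 1000.0 / config.generator.sampling_rate_hz
    w0, w1 = config.window_ms
    grid = w0 + np.arange(int(round((w1 - w0) / dt))) * dt
    sw = (grid >= config.stats_window_ms[0]) & (grid < config.stats_window_ms[1])
    stats_seed = int(np.random.SeedSequence([config.seed, 997]).
                     generate_state(1)[0] % (2 ** 31))

    cluster_results = {}
    rate_mats = {}
    for lock in config.locks:
        both = [r for r in results
                if (lock, "sound") in r.rate_curves
                and (lock, "baseline") in r.rate_curves]
        if len(both) >= 2:
            A = np.vstack([r.rate_curves[(lock, "sound")] for r in both])
            B = np.vstack([r.rate_curves[(lock, "baseline")] for r in both])
            rate_mats[(lock, "sound")] = A
            rate_mats[(lock, "baseline")] = B
            cluster_results[f"ms_rate_{lock}"] = cl.permutation_test(
                A[:, sw], B[:, sw], config.n_iterations, config.alpha,
                seed=stats_seed, grid_ms=grid[sw])

    pupil_mats = {}
    with_pupil = [r for r in results
                  if "sound" in r.pupil_curves and "baseline" in r.pupil_curves]
    if len(with_pupil) >= 2:
        A = np.vstack([r.pupil_curves["sound"] for r in with_pupil])
        B = np.vstack([r.pupil_curves["baseline"] for r in with_pupil])
        pupil_mats["sound"] = A
        pupil_mats["baseline"] = B
        cluster_results["pupil_frame1"] = cl.permutation_test(
            A[:, sw], B[:, sw], config.n_iterations, config.alpha,
            seed=stats_seed, grid_ms=grid[sw])

    # S1-S4 segment means per participant and condition
    scheme = rates.SegmentScheme()
    seg_rows = []
    for r in results:
        for (lock, cond), curve in r.rate_curves.items():
            segs = rates.bin_segments(rates.RateCurve(grid, curve, 0), scheme)
            seg_rows.append({"session_id": r.session_id, "measure": "ms_rate",
                             "lock": lock, "condition": cond, **segs})
        for cond, curve in r.pupil_curves.items():
            segs = rates.bin_segments(rates.RateCurve(grid, curve, 0), scheme)
            seg_rows.append({"session_id": r.session_id, "measure": "pupil",
                             "lock": "frame1", "condition": cond, **segs})
    segment_means = pd.DataFrame(seg_rows)

    # psychometric table
    psy_rows = []
    for r in results:
        for cond, fit in r.psychometric.items():
            psy_rows.append({
                "session_id": r.session_id, "condition": cond,
                "pse_ms": fit.pse_ms if fit.converged else np.nan,
                "jnd_ms": fit.jnd_ms if fit.converged else np.nan,
                "converged": fit.converged, "extrapolated": fit.extrapolated,
            })
    psy_df = pd.DataFrame(psy_rows)

    # pooled main sequence
    all_events = [e for r in results for e in r.events]
    try:
        r_ms, n_ev = det.main_sequence(all_events)
    except ValueError:
        r_ms, n_ev = np.nan, len(all_events)

    # delta correlation: late-window OMI change vs group-motion change
    delta = None
    usable = [r for r in results
              if ("frame1", "sound") in r.rate_curves
              and ("frame1", "baseline") in r.rate_curves
              and "sound" in r.group_motion and "baseline" in r.group_motion]
    if len(usable) >= 3:
        late = (grid >= 500.0) & (grid < 1000.0)
        d_rate = [float((r.rate_curves[("frame1", "sound")][late]
                         - r.rate_curves[("frame1", "baseline")][late]).mean())
                  for r in usable]
        d_beh = [r.group_motion["sound"] - r.group_motion["baseline"]
                 for r in usable]
        try:
            delta = cl.delta_correlation(d_rate, d_beh)
        except ValueError:
            delta = None

    gaze_all = pd.concat(
        [r.gaze_durations.assign(session_id=r.session_id) for r in results],
        ignore_index=True)

    return AnalysisReport(
        config=config.snapshot(), psychometrics=psy_df,
        gaze_durations=gaze_all, main_sequence_r=r_ms, n_events=n_ev,
        cluster_results=cluster_results, segment_means=segment_means,
        delta_correlation=delta, rate_grid_ms=grid, rate_curves=rate_mats,
        pupil_curves=pupil_mats)


def write_report(report: AnalysisReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.psychometrics.to_csv(out / "psychometrics.csv", index=False)
    report.gaze_durations.to_csv(out / "gaze_durations.csv", index=False)
    report.segment_means.to_csv(out / "segment_means.csv", index=False)
    rows = []
    for (lock, cond), mat in report.rate_curves.items():
        mean = mat.mean(axis=0)
        se = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
        for t, m, s in zip(report.rate_grid_ms, mean, se):
            rows.append({"measure": "ms_rate", "lock": lock, "condition": cond,
                         "time_ms": t, "value": m, "se": s})
    for cond, mat in report.pupil_curves.items():
        mean = mat.mean(axis=0)
        se = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
        for t, m, s in zip(report.rate_grid_ms, mean, se):
            rows.append({"measure": "pupil", "lock": "frame1",
                         "condition": cond, "time_ms": t, "value": m, "se": s})
    pd.DataFrame(rows).to_csv(out / "curves.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True, default=float)


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full pipeline and (optionally) write its artifacts."""
    if config.dataset_dir:
        sessions = load_dataset(config.dataset_dir)
    else:
        sessions = simulate_dataset(config)
    if not sessions or all(not s.trials for s in sessions):
        raise PipelineError("ingestion: empty dataset (no sessions/trials)")
    results = []
    for s in sessions:
        try:
            results.append(analyze_session(s, config))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"session {s.session_id}: {exc}") from exc
    report = group_analysis(results, config)
    if config.out_dir:
        write_report(report, config.out_dir)
        events = det.events_to_frame([e for r in results for e in r.events])
        events.to_csv(Path(config.out_dir) / "events.csv", index=False)
    return report
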