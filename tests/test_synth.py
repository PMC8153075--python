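"""Statistical structure of the synthetic behavioral and gaze generator."""

import dataclasses

import numpy as np
import pytest

import ternuseye as te
from ternuseye.design import ExperimentDesign, TrialSpec
from ternuseye.synth import pupil_impulse_response


def _flat_trials(n, soa=170.0, sound=False, with_frames=True):
    """n identical trials with a minimal timeline (frame1 at 4000 ms)."""
    trials = []
    for i in range(n):
        tl = {"fixation": 0.0, "probe": 4000.0 + soa + 330.0}
        if with_frames:
            tl["frame1"] = 4000.0
            tl["frame2"] = 4000.0 + soa
            if sound:
                tl["beep1"] = 4000.0
                tl["beep2"] = 4000.0 + soa
        else:
            tl["beep1"] = 4000.0
            tl["beep2"] = 4000.0 + soa
        trials.append(TrialSpec(i, soa, sound, "left", 0, tl))
    return ExperimentDesign("E1", trials, [(0, "mixed")])


def test_group_motion_proportion_half_at_pse(default_params):
    pse = default_params.psychometric.pse_baseline_ms
    design = _flat_trials(10_000, soa=pse)
    df = te.sample_behavior(design, default_params, seed=1)
    assert df["group_motion"].mean() == pytest.approx(0.5, abs=0.015)


def test_group_motion_saturates_at_long_soa(default_params):
    design = _flat_trials(2000, soa=1500.0)
    df = te.sample_behavior(design, default_params, seed=2)
    assert df["group_motion"].mean() > 0.995


def test_invalid_jnd_rejected(default_params):
    bad = dataclasses.replace(default_params.psychometric, jnd_sound_ms=-1.0)
    params = dataclasses.replace(default_params, psychometric=bad)
    with pytest.raises(ValueError, match="jnd"):
        te.sample_behavior(_flat_trials(5), params, seed=0)


def test_e4_reaction_times_by_condition(default_params):
    design_base = te.build_design("E4", seed=3)
    df = te.sample_behavior(design_base, default_params, seed=3)
    assert "rt_ms" in df.columns and "group_motion" not in df.columns
    rt = df.groupby("sound")["rt_ms"].mean()
    assert rt[True] < rt[False]
    assert (df["rt_ms"] >= default_params.rt.lower_bound_ms).all()


def test_psychometric_recovery_loop(default_params):
    """Generator + fitter are mutual inverses at large trial counts."""
    soas = np.array(te.SOA_LEVELS_MS)
    for cond, true_pse, true_jnd in (
            ("baseline", 180.1, 37.9), ("sound", 100.2, 42.6)):
        design = ExperimentDesign("E1", [
            t for soa in soas for t in _flat_trials(
                2000, soa=soa, sound=(cond == "sound")).trials], [])
        df = te.sample_behavior(design, default_params, seed=5)
        agg = df.groupby("soa_ms")["group_motion"].agg(["sum", "count"])
        fit = te.fit_logistic(agg.index.to_numpy(), agg["sum"].to_numpy(),
                              agg["count"].to_numpy())
        assert fit.converged
        assert fit.pse_ms == pytest.approx(true_pse, abs=2.5)
        assert fit.jnd_ms == pytest.approx(true_jnd, abs=3.0)


def test_homogeneous_event_rate_matches_base_rate(default_params):
    """With modulation off the generator is a homogeneous point process."""
    ms = dataclasses.replace(default_params.ms_process, inhib_depth=0.0,
                             rebound_gain=0.0, sound_late_depth=0.0)
    params = dataclasses.replace(default_params, ms_process=ms)
    trial = _flat_trials(1).trials[0]
    n_trials, count = 600, 0
    lo, hi = 3500.0, 4500.0  # interior 1-s window, away from edge margins
    for i in range(n_trials):
        rec = te.simulate_gaze_trial(trial, params, seed=i)
        count += sum(1 for e in rec.meta["injected_events"]
                     if lo <= e["onset_ms"] < hi)
    mean = count / n_trials
    se = np.sqrt(1.5 / n_trials)  # Poisson SE of the per-trial mean
    assert abs(mean - 1.5) < 3 * se + 0.05  # small deficit from the 20-ms gap


def test_detector_round_trip_recovers_injections(default_params):
    """>= 90% of injected events detected with onset error <= 1 sample."""
    trial = _flat_trials(1).trials[0]
    recs = [te.simulate_gaze_trial(trial, default_params, seed=i)
            for i in range(300)]
    stats = te.session_stats([te.compute_velocity(r)[0] for r in recs])
    n_inj, hit = 0, 0
    for rec in recs:
        events = te.detect_microsaccades(rec, stats)
        onsets = np.array([e.onset_ms for e in events])
        for inj in rec.meta["injected_events"]:
            n_inj += 1
            if onsets.size and np.min(np.abs(onsets - inj["onset_ms"])) <= 2.0001:
                hit += 1
    assert n_inj > 300
    assert hit / n_inj >= 0.90


def test_injected_main_sequence_correlation(default_params):
    trial = _flat_trials(1).trials[0]
    amps, vels = [], []
    for i in range(200):
        rec = te.simulate_gaze_trial(trial, default_params, seed=i)
        for e in rec.meta["injected_events"]:
            amps.append(e["amplitude_deg"])
            vels.append(e["peak_velocity_deg_s"])
    r = np.corrcoef(amps, vels)[0, 1]
    assert r >= 0.7


def test_window_must_cover_analysis_epoch(default_params):
    trial = _flat_trials(1).trials[0]
    with pytest.raises(ValueError, match="window"):
        te.simulate_gaze_trial(trial, default_params, seed=0,
                               window_ms=(-200.0, 1600.0))
    with pytest.raises(ValueError, match="divisible"):
        te.simulate_gaze_trial(trial, default_params, seed=0,
                               window_ms=(-1200.0, 1600.5))


def test_pupil_noise_free_trace_is_impulse_response(default_params):
    """noise = 0, no blinks, single visual event -> exact impulse response."""
    pp = dataclasses.replace(default_params.pupil, noise_sd_au=0.0,
                             blink_rate_hz=0.0)
    params = dataclasses.replace(default_params, pupil=pp)
    trial = TrialSpec(0, 170.0, False, "left", 0,
                      {"fixation": 0.0, "frame1": 4000.0, "probe": 5000.0})
    rec = te.simulate_gaze_trial(trial, params, seed=0)
    te.simulate_pupil_trial(trial, rec, params, seed=0)
    expected = pp.baseline_au + pp.response_gain_au * pupil_impulse_response(
        rec.time_ms - 4000.0, pp.time_to_peak_ms, pp.shape_n)
    np.testing.assert_allclose(rec.pupil, expected, rtol=0, atol=1e-12)


def test_zero_sound_gain_gives_null_condition_difference(default_params):
    """With sound_gain = 0 the sound/baseline pupil ensembles coincide."""
    from scipy import stats as sps
    pp = dataclasses.replace(default_params.pupil, sound_gain_au=0.0,
                             blink_rate_hz=0.0)
    params = dataclasses.replace(default_params, pupil=pp)
    means = {True: [], False: []}
    for i in range(120):
        sound = i % 2 == 0
        trial = _flat_trials(1, sound=sound).trials[0]
        rec = te.simulate_gaze_trial(trial, params, seed=i)
        te.simulate_pupil_trial(trial, rec, params, seed=1000 + i)
        m = (rec.time_ms >= 4250.0) & (rec.time_ms < 5000.0)
        means[sound].append(np.nanmean(rec.pupil[m]))
    _, p = sps.ttest_ind(means[True], means[False])
    assert p > 0.01


def test_negative_noise_sd_rejected(default_params):
    pp = dataclasses.replace(default_params.pupil, noise_sd_au=-1.0)
    params = dataclasses.replace(default_params, pupil=pp)
    trial = _flat_trials(1).trials[0]
    rec = te.simulate_gaze_trial(trial, default_params, seed=0)
    with pytest.raises(ValueError, match="noise_sd"):
        te.simulate_pupil_trial(trial, rec, params, seed=0)


def test_generation_is_pure_function_of_params_and_seed(default_params):
    trial = _flat_trials(1, sound=True).trials[0]
    a = te.simulate_gaze_trial(trial, default_params, seed=9)
    b = te.simulate_gaze_trial(trial, default_params, seed=9)
    np.testing.assert_array_equal(a.x_deg, b.x_deg)
    np.testing.assert_array_equal(a.y_deg, b.y_deg)
    c = te.simulate_gaze_trial(trial, default_params, seed=10)
    assert not np.array_equal(a.x_deg, c.x_deg)


class TestGenerateDataset:
    def test_manifest_round_trip_byte_identical(self, tmp_path, default_params):
        from ternuseye.synth import generate_dataset, regenerate_from_manifest
        out1 = tmp_path / "d1"
        man1 = generate_dataset(default_params, ["E1"], 2, out1, seed=5,
                                trials_per_cell=1)
        assert len([k for k in man1["files"] if "samples" in k]) == 2 * 14
        out2 = tmp_path / "d2"
        man2 = regenerate_from_manifest(man1, out2)
        assert man1["files"] == man2["files"]

    def test_zero_subjects_rejected(self, tmp_path, default_params):
        from ternuseye.synth import generate_dataset
        with pytest.raises(ValueError, match="n_subjects"):
            generate_dataset(default_params, ["E1"], 0, tmp_path)

    def test_parameter_change_changes_checksums(self, tmp_path, default_params):
        from ternuseye.synth import generate_dataset
        man1 = generate_dataset(default_params, ["E1"], 1, tmp_path / "a",
                                seed=5, trials_per_cell=1)
        params2 = dataclasses.replace(
            default_params,
            ms_process=dataclasses.replace(default_params.ms_process,
                                           base_rate_hz=2.5))
        man2 = generate_dataset(params2, ["E1"], 1, tmp_path / "b",
                                seed=5, trials_per_cell=1)
        assert man1["files"] != man2["files"]
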