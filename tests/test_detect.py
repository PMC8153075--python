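"""Velocity estimation, thresholding, event filters, and the main sequence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ternuseye as te
from ternuseye.detect import (DetectionParams, MicrosaccadeEvent,
                              VelocityStats, detect_candidates, filter_events,
                              main_sequence, median_sd)


def _rec(x, y=None, dt=2.0):
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    n = len(x)
    return te.GazeRecording(np.arange(n) * dt, x, y, np.full(n, np.nan),
                            sampling_rate_hz=1000.0 / dt)


class TestVelocity:
    def test_constant_position_zero_velocity(self):
        vx, vy = te.compute_velocity(_rec(np.ones(20)))
        assert np.allclose(vx[2:-2], 0.0) and np.allclose(vy[2:-2], 0.0)
        assert np.isnan(vx[:2]).all() and np.isnan(vx[-2:]).all()

    def test_linear_ramp_is_exact(self):
        # x(t) = 3 deg/s * t: the window estimator is exact on linear signals
        t_s = np.arange(30) * 0.002
        vx, _ = te.compute_velocity(_rec(3.0 * t_s))
        assert np.allclose(vx[2:-2], 3.0, atol=1e-9)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="5-sample"):
            te.compute_velocity(_rec(np.zeros(4)))


class TestMedianSD:
    def test_hand_computed_example(self):
        # median(v^2) = 9, median(v) = 0 -> sigma = 3
        s = median_sd(np.array([0.0, 0.0, 3.0, 4.0, -3.0]))
        assert s.sigma_x == pytest.approx(3.0)
        assert not s.degenerate

    def test_constant_velocity_degenerate(self):
        s = median_sd(np.full(10, 2.5))
        assert s.sigma_x == 0.0 and s.degenerate

    def test_sign_flip_invariance(self):
        # the median-based estimator is even in v (but NOT translation
        # invariant: for an all-positive sample median(v^2) = median(v)^2)
        rng = np.random.default_rng(3)
        v = rng.normal(0, 1, 101)
        assert median_sd(-v).sigma_x == pytest.approx(
            median_sd(v).sigma_x, abs=1e-12)
        assert median_sd(v + 100.0).degenerate

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            median_sd(np.array([np.nan]))


def _stats(sigma=1.0, lam=8.0):
    return VelocityStats(sigma_x=sigma, threshold=lam * sigma,
                         degenerate=False, sigma_y=sigma)


class TestCandidates:
    def test_zero_velocity_no_candidates(self):
        assert detect_candidates(np.zeros(100), _stats()) == []

    def test_single_injected_excursion(self):
        v = np.zeros(200)
        v[50:55] = 20.0  # 10 ms at 2-ms sampling
        evs = detect_candidates(v, _stats(sigma=1.0))
        assert len(evs) == 1
        assert evs[0].onset_ms == pytest.approx(100.0)
        assert evs[0].duration_ms == pytest.approx(10.0)

    def test_huge_lambda_removes_everything(self):
        v = np.zeros(100)
        v[40:50] = 50.0
        params = DetectionParams(lambda_threshold=1e6)
        assert detect_candidates(v, _stats(), params) == []

    def test_degenerate_stats_rejected(self):
        s = VelocityStats(0.0, 0.0, True)
        with pytest.raises(ValueError, match="degenerate"):
            detect_candidates(np.zeros(10), s)

    def test_lambda_monotonicity(self):
        rng = np.random.default_rng(7)
        v = rng.normal(0, 1, 2000)
        lo = detect_candidates(v, _stats(lam=2.0),
                               DetectionParams(lambda_threshold=2.0))
        hi = detect_candidates(v, _stats(lam=3.0),
                               DetectionParams(lambda_threshold=3.0))
        lo_spans = {(e.onset_ms, e.offset_ms) for e in lo}
        for e in hi:
            # every high-threshold event lies inside some low-threshold run
            assert any(s <= e.onset_ms and e.offset_ms <= t
                       for s, t in lo_spans)

    def test_equivalence_with_brute_force_oracle(self):
        """1000 random traces against an index-by-index reference scan."""
        rng = np.random.default_rng(11)
        params = DetectionParams()
        for _ in range(1000):
            n = int(rng.integers(10, 60))
            v = rng.normal(0, 1, n) * rng.choice([1.0, 4.0], n)
            stats = _stats(sigma=1.0)
            got = [(e.onset_ms, e.offset_ms)
                   for e in detect_candidates(v, stats, params)]
            # oracle: naive scan for runs of |v| > 8 with >= 2 samples
            exp = []
            i = 0
            while i < n:
                if abs(v[i]) > 8.0:
                    j = i
                    while j < n and abs(v[j]) > 8.0:
                        j += 1
                    if j - i >= 2:
                        exp.append((i * 2.0, j * 2.0))
                    i = j
                else:
                    i += 1
            assert got == exp


def _cand(onset, dur):
    return MicrosaccadeEvent(onset, onset + dur, dur)


class TestFilter:
    def test_duration_rule(self):
        cands = [_cand(0, 2), _cand(500, 10), _cand(1000, 115), _cand(1500, 40)]
        kept = filter_events(cands)
        assert [k.duration_ms for k in kept] == [10, 40]

    def test_interval_rule_keeps_earlier(self):
        cands = [_cand(0, 10), _cand(25, 10)]  # offset 10 -> gap 15 ms
        kept = filter_events(cands)
        assert len(kept) == 1 and kept[0].onset_ms == 0

    def test_onset_to_onset_variant(self):
        cands = [_cand(0, 10), _cand(25, 10)]
        kept = filter_events(cands, DetectionParams(interval_rule="onset_to_onset"))
        assert len(kept) == 2  # 25 ms onset-to-onset >= 20 ms

    def test_empty_input(self):
        assert filter_events([]) == []

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            filter_events([_cand(100, 10), _cand(0, 10)])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 5000), st.floats(1, 150)),
                    max_size=20))
    def test_subset_intervals_and_idempotence(self, raw):
        cands = sorted((_cand(o, d) for o, d in raw), key=lambda c: c.onset_ms)
        kept = filter_events(cands)
        assert all(k in cands for k in kept)
        for a, b in zip(kept, kept[1:]):
            assert b.onset_ms - a.offset_ms >= 20.0
        assert filter_events(kept) == kept


class TestProperties:
    def test_horizontal_step_amplitude(self):
        x = np.concatenate([np.zeros(10), np.full(10, 0.5)])
        rec = _rec(x)
        vx, vy = te.compute_velocity(rec)
        ev = MicrosaccadeEvent(16.0, 24.0, 8.0)  # samples 8..11 cover the step
        te.event_properties(rec, ev, vx, vy)
        assert ev.amplitude_deg == pytest.approx(0.5)
        assert ev.peak_velocity_deg_s > 0

    def test_scaling_positions_scales_amplitude_and_velocity(self):
        rng = np.random.default_rng(5)
        x = np.cumsum(rng.normal(0, 0.01, 40))
        x[20:25] += np.linspace(0, 0.4, 5)
        for scale in (1.0, 2.0):
            rec = _rec(scale * x)
            vx, vy = te.compute_velocity(rec)
            ev = MicrosaccadeEvent(40.0, 50.0, 10.0)
            te.event_properties(rec, ev, vx, vy)
            if scale == 1.0:
                a1, v1 = ev.amplitude_deg, ev.peak_velocity_deg_s
        assert ev.amplitude_deg == pytest.approx(2 * a1)
        assert ev.peak_velocity_deg_s == pytest.approx(2 * v1)

    def test_zero_displacement_jitter(self):
        x = np.zeros(40)
        x[20] = 0.001  # one-sample twitch, returns to start
        rec = _rec(x)
        vx, vy = te.compute_velocity(rec)
        ev = MicrosaccadeEvent(38.0, 44.0, 6.0)
        te.event_properties(rec, ev, vx, vy)
        assert ev.amplitude_deg == pytest.approx(0.0, abs=1e-6)


def _ev(a, v):
    return MicrosaccadeEvent(0, 10, 10, amplitude_deg=a, peak_velocity_deg_s=v)


class TestMainSequence:
    def test_exact_line_gives_unit_correlation(self):
        evs = [_ev(a, 60 * a) for a in (0.1, 0.4, 0.7, 1.2)]
        r, n = main_sequence(evs)
        assert r == pytest.approx(1.0) and n == 4

    def test_four_point_toy_set_matches_direct_formula(self):
        amps = np.array([1.0, 2.0, 3.0, 4.0])
        vels = np.array([10.0, 18.0, 33.0, 38.0])
        # independent oracle: covariance formula written out by hand
        ax, vx_ = amps - amps.mean(), vels - vels.mean()
        r_oracle = (ax * vx_).sum() / np.sqrt((ax ** 2).sum() * (vx_ ** 2).sum())
        r, _ = main_sequence([_ev(a, v) for a, v in zip(amps, vels)])
        assert r == pytest.approx(r_oracle, abs=1e-12)
        assert r == pytest.approx(0.98338, abs=1e-4)

    def test_too_few_or_degenerate(self):
        with pytest.raises(ValueError):
            main_sequence([_ev(1, 10), _ev(2, 20)])
        with pytest.raises(ValueError, match="variance"):
            main_sequence([_ev(1, 10), _ev(1, 20), _ev(1, 30)])
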