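"""Gaze angles, angular velocity, adaptive threshold, event parsing."""

import numpy as np
import pytest

from gazeshelf.preprocess import (
    GazeEvent,
    SaccadeDetectionParams,
    VelocityTrace,
    adaptive_saccade_threshold,
    classify_and_merge,
    compute_angular_velocity,
    compute_gaze_angles,
    filter_fixations,
    merge_events,
)

P = SaccadeDetectionParams()


def make_trace(omega, rate=100.0):
    omega = np.asarray(omega, dtype=float)
    t = np.arange(1, len(omega) + 1) / rate
    return VelocityTrace(t=t, omega_h=omega, omega_v=np.zeros_like(omega),
                         omega=omega, t_prev=t - 1 / rate)


class TestGazeAngles:
    @pytest.mark.parametrize(
        "direction, expected",
        [
            ((0, 0, 1), (0.0, 0.0)),
            ((1 / np.sqrt(2), 0, 1 / np.sqrt(2)), (45.0, 0.0)),
            ((0, 1 / np.sqrt(2), 1 / np.sqrt(2)), (0.0, 45.0)),
        ],
    )
    def test_reference_directions(self, direction, expected):
        th, tv, valid = compute_gaze_angles(np.array([direction]))
        assert valid[0]
        assert th[0] == pytest.approx(expected[0], abs=1e-9)
        assert tv[0] == pytest.approx(expected[1], abs=1e-9)

    def test_zero_forward_component_flagged_invalid(self):
        th, tv, valid = compute_gaze_angles(np.array([[1.0, 0.0, 0.0]]))
        assert not valid[0] and np.isnan(th[0])


class TestAngularVelocity:
    def test_constant_angles_give_zero(self):
        t = np.arange(10) / 100
        trace = compute_angular_velocity(t, np.full(10, 5.0), np.full(10, -3.0))
        assert np.allclose(trace.omega, 0)

    def test_ramp_velocity(self):
        # 10 degrees per sample at 100 Hz -> 1000 deg/s
        t = np.arange(10) / 100
        trace = compute_angular_velocity(t, 10.0 * np.arange(10), np.zeros(10))
        assert np.allclose(trace.omega, 1000.0)

    def test_sinusoid_matches_analytic_derivative(self):
        rate = 1000.0
        t = np.arange(0, 1, 1 / rate)
        theta = 5 * np.sin(2 * np.pi * 2 * t)
        trace = compute_angular_velocity(t, theta, np.zeros_like(t))
        analytic = np.abs(5 * 2 * np.pi * 2 * np.cos(2 * np.pi * 2 * (t[1:] - 0.5 / rate)))
        assert np.allclose(trace.omega, analytic, atol=0.05 * analytic.max())

    def test_duplicate_timestamp_names_index(self):
        t = np.array([0.0, 0.01, 0.01, 0.03])
        with pytest.raises(ValueError, match="index 2"):
            compute_angular_velocity(t, np.zeros(4), np.zeros(4))


class TestAdaptiveThreshold:
    def test_all_zero_trace_converges_to_zero(self):
        theta, n = adaptive_saccade_threshold(make_trace(np.zeros(100)), P)
        assert theta == 0.0

    def test_bimodal_trace_threshold_between_modes(self, rng):
        fix = np.abs(rng.normal(10, 3, 500))
        sac = rng.normal(400, 30, 40)
        theta, _ = adaptive_saccade_threshold(make_trace(np.concatenate([fix, sac])), P)
        assert np.percentile(fix, 90) < theta < sac.min()

    def test_all_supra_threshold_returns_initial_with_warning(self):
        with pytest.warns(UserWarning):
            theta, _ = adaptive_saccade_threshold(make_trace(np.full(50, 500.0)), P)
        assert theta == P.theta0

    def test_threshold_unchanged_by_high_velocity_samples(self, rng):
        fix = np.abs(rng.normal(10, 3, 500))
        base, _ = adaptive_saccade_threshold(make_trace(fix), P)
        spiked = np.concatenate([fix, np.full(30, base + 500)])
        again, _ = adaptive_saccade_threshold(make_trace(spiked), P)
        assert again == pytest.approx(base, abs=P.convergence_tol)


def events_ms(*spec):
    """Build adjacent events from (kind, duration_ms) pairs."""
    out = []
    t = 0.0
    for kind, ms in spec:
        out.append(GazeEvent(kind, t, t + ms / 1000))
        t += ms / 1000
    return out


class TestMergeRules:
    def test_short_saccade_absorbed_between_fixations(self):
        merged = merge_events(events_ms(("fixation", 500), ("saccade", 20), ("fixation", 500)), P)
        assert len(merged) == 1
        assert merged[0].kind == "fixation"
        assert merged[0].duration == pytest.approx(1.020)

    def test_short_fixation_absorbed_between_saccades(self):
        merged = merge_events(events_ms(("saccade", 40), ("fixation", 40), ("saccade", 40)), P)
        assert len(merged) == 1
        assert merged[0].kind == "saccade"
        assert merged[0].duration == pytest.approx(0.120)

    def test_long_saccade_not_merged(self):
        evs = events_ms(("fixation", 500), ("saccade", 40), ("fixation", 500))
        assert len(merge_events(evs, P)) == 3

    def test_merge_is_idempotent(self, rng):
        for _ in range(50):
            kinds = rng.choice(["fixation", "saccade"], size=rng.integers(2, 12))
            durs = rng.integers(5, 200, size=len(kinds))
            evs = events_ms(*zip(kinds, durs))
            once = merge_events(evs, P)
            twice = merge_events(once, P)
            assert [(e.kind, e.onset, e.end) for e in once] == [
                (e.kind, e.onset, e.end) for e in twice
            ]

    def test_classification_from_velocity_runs(self):
        # 500 ms fixation, 20 ms saccade, 500 ms fixation at 1 kHz
        omega = np.concatenate([np.zeros(500), np.full(20, 400.0), np.zeros(500)])
        trace = make_trace(omega, rate=1000.0)
        events = classify_and_merge(trace, threshold=100.0, params=P)
        assert len(events) == 1 and events[0].kind == "fixation"

    def test_recording_gap_splits_events(self):
        t = np.concatenate([np.arange(50) / 100, 1.0 + np.arange(50) / 100])
        trace = compute_angular_velocity(t, np.zeros(100), np.zeros(100))
        events = classify_and_merge(trace, threshold=10.0, params=P)
        assert len(events) == 2
        assert all(e.kind == "fixation" for e in events)


class TestFixationFilter:
    def test_minimum_duration_rule(self):
        evs = events_ms(("fixation", 80), ("fixation", 300), ("fixation", 310), ("fixation", 320))
        kept, report = filter_fixations(evs, P)
        assert report["n_short"] == 1
        assert all(e.duration >= 0.100 for e in kept)

    def test_identical_durations_skip_outlier_rule(self):
        evs = events_ms(*[("fixation", 300)] * 10)
        with pytest.warns(UserWarning, match="MAD is zero"):
            kept, report = filter_fixations(evs, P)
        assert len(kept) == 10 and report["rejection_fraction"] == 0

    def test_extreme_outlier_rejected(self, rng):
        durs = list(rng.integers(280, 420, size=60)) + [5000]
        evs = events_ms(*[("fixation", d) for d in durs])
        kept, report = filter_fixations(evs, P)
        assert report["n_outlier"] >= 1
        assert max(e.duration for e in kept) < 5.0
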