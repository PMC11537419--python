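"""Synthetic-session generator: stream invariants, determinism, agent
policies, parameter recovery, and ground-truth round trips."""

import numpy as np
import pandas as pd
import pytest

from gazeshelf import (
    AgentPolicy,
    GeneratorConfig,
    INSTRUCTIONS,
    generate_initial_configuration,
    greedy_solve,
    is_goal,
    process_trial,
    simulate_agent_moves,
    simulate_session,
)
from gazeshelf.shelf import ShelfState


class TestAgentPolicies:
    @pytest.mark.parametrize("kind", ["greedy_optimal", "spatial_heuristic", "random_valid"])
    def test_moves_are_legal_and_reach_goal(self, kind, rng):
        """Legality of every generated move, checked over >= 10^4 moves."""
        total = 0
        solved = 0
        n_trials = 0
        while total < 10_000:
            state = generate_initial_configuration(rng)
            ins = list(INSTRUCTIONS.values())[n_trials % 12]
            moves, ok = simulate_agent_moves(state, ins, AgentPolicy(kind), rng)
            s = state
            for mv in moves:
                s = s.apply(mv)          # raises on any illegal move
                assert mv.from_cell != mv.to_cell
            if ok:
                assert is_goal(s, ins)
                solved += 1
            total += max(len(moves), 1)
            n_trials += 1
        assert solved / n_trials > 0.7

    def test_already_sorted_state_yields_no_moves(self, rng):
        state = generate_initial_configuration(rng)
        ins = INSTRUCTIONS["easy_row_same_color"]
        res = greedy_solve(state, ins)
        if not res.solved:
            pytest.skip("instance not solvable by steepest ascent")
        s = state
        for mv in res.move_sequence:
            s = s.apply(mv)
        moves, ok = simulate_agent_moves(s, ins, AgentPolicy("greedy_optimal"), rng)
        assert ok and moves == []

    def test_greedy_agent_replays_solver_optimum(self, rng):
        for _ in range(10):
            state = generate_initial_configuration(rng)
            ins = INSTRUCTIONS["easy_col_same_shape"]
            moves, _ = simulate_agent_moves(state, ins, AgentPolicy("greedy_optimal"), rng)
            assert len(moves) == greedy_solve(state, ins).n_moves

    def test_spatial_heuristic_progresses_top_left_to_bottom_right(self, rng):
        """Pickup location drifts down/right as the trial progresses."""
        from scipy.stats import spearmanr

        rows, idxs = [], []
        for k in range(60):
            state = generate_initial_configuration(rng)
            ins = list(INSTRUCTIONS.values())[k % 12]
            moves, _ = simulate_agent_moves(state, ins, AgentPolicy("spatial_heuristic"), rng)
            for i, mv in enumerate(moves):
                rows.append(mv.from_cell[0] + mv.from_cell[1])
                idxs.append(i)
        rho, p = spearmanr(rows, idxs)
        assert rho > 0.2 and p < 0.001


class TestStreams:
    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig()
        a = simulate_session(cfg, n_subjects=1, seed=9)[0]
        b = simulate_session(cfg, n_subjects=1, seed=9)[0]
        for ta, tb in zip(a.trials, b.trials):
            assert np.array_equal(ta.gaze_dir, tb.gaze_dir)
            assert np.array_equal(ta.t_gaze, tb.t_gaze)
            assert np.array_equal(ta.ctrl_pos, tb.ctrl_pos)
            assert ta.instruction.id == tb.instruction.id

    def test_stream_invariants(self, noisy_cohort):
        _, sessions = noisy_cohort
        for tr in sessions[0].trials:
            assert np.all(np.diff(tr.t_gaze) > 0)
            assert np.allclose(np.linalg.norm(tr.gaze_dir, axis=1), 1.0, atol=1e-6)
            # trigger transitions are paired: press precedes release
            edges = np.diff(tr.trigger.astype(int))
            presses = np.where(edges == 1)[0]
            releases = np.where(edges == -1)[0]
            assert len(presses) == len(releases)
            assert np.all(presses < releases)

    def test_session_structure(self, noisy_cohort):
        _, sessions = noisy_cohort
        for sess in sessions:
            ids = [tr.instruction.id for tr in sess.trials]
            assert len(ids) == 24
            assert all(ids.count(i) == 2 for i in INSTRUCTIONS)

    def test_epoch_duration_parameter_recovery(self, noisy_cohort):
        """Ground-truth epoch durations recover the configured means."""
        cfg, sessions = noisy_cohort
        rows = [
            {"trial_type": tr.trial_type, "kind": ep.kind, "duration": ep.duration}
            for s in sessions for tr in s.trials for ep in tr.truth_epochs
        ]
        df = pd.DataFrame(rows)
        for ttype in ("EASY", "HARD"):
            prep = df[(df.trial_type == ttype) & (df.kind == "preparation")].duration.mean()
            exe = df[(df.trial_type == ttype) & (df.kind == "execution")].duration.mean()
            assert prep == pytest.approx(cfg.prep_mean[ttype], rel=0.08)
            assert exe == pytest.approx(cfg.exec_mean[ttype], rel=0.08)


class TestRoundTrip:
    def test_noise_free_recovery_is_exact(self, clean_session):
        """Detection + labeling recovers every ground-truth fixation >= 100 ms
        (onset within one sample, same cell and ROI) and every grasp."""
        cfg, sessions = clean_session
        dt = 1 / cfg.sample_rate
        n_truth = n_matched = 0
        for tr in sessions[0].trials:
            out = process_trial(tr, apply_duration_filter=False)
            fx = out["fixations"]
            truth = tr.truth_fixations
            if len(truth) == 0:
                continue
            truth = truth[truth.duration >= 0.100]
            for t_ in truth.itertuples():
                n_truth += 1
                cand = fx[(fx.onset - t_.onset).abs() <= dt * 1.001]
                if len(cand):
                    c = cand.iloc[0]
                    if (c.row, c.col) == (t_.row, t_.col) and c.roi == t_.roi:
                        n_matched += 1
            # grasps: cells exact, times within ~1 sample
            det = out["grasps"]
            assert len(det) == len(tr.truth_grasps)
            for d, g in zip(det, tr.truth_grasps):
                assert d.pickup_cell == g.pickup_cell
                assert d.dropoff_cell == g.dropoff_cell
                assert abs(d.onset - g.onset) <= 1.5 * dt
                assert abs(d.end - g.end) <= 1.5 * dt
            # epochs tile identically to ground truth
            for de, ge in zip(out["epochs"], tr.truth_epochs):
                assert de.kind == ge.kind
                assert abs(de.start - ge.start) <= 1.5 * dt
                assert abs(de.end - ge.end) <= 1.5 * dt
        assert n_truth > 500
        assert n_matched == n_truth

    def test_duration_outlier_rejection_near_configured_rate(self, noisy_cohort):
        """The upper-fence filter trims about the calibrated ~2.4% share."""
        _, sessions = noisy_cohort
        fracs = [
            process_trial(tr)["report"]["rejection_fraction"]
            for tr in sessions[0].trials[:12]
        ]
        assert 0.005 < np.mean(fracs) < 0.06

    def test_solved_initial_state_yields_zero_moves(self, rng):
        from gazeshelf.shelf import COLORS, SHAPES, ObjectSpec

        # hand-build a solved configuration: color-group rows
        grid = {}
        for r, color in enumerate(COLORS, start=1):
            for c, shape in enumerate(SHAPES, start=1):
                grid[(r, c)] = ObjectSpec(color, shape)
        ins = INSTRUCTIONS["easy_row_same_color"]
        moves, ok = simulate_agent_moves(ShelfState(grid), ins, AgentPolicy(), rng)
        assert ok and moves == []
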