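"""Time-locked profiles, cluster permutation testing, transition
matrices, first-fixation latencies."""

import numpy as np
import pandas as pd
import pytest

from gazeshelf.dynamics import (
    N_BINS,
    cluster_permutation_test,
    first_fixation_latencies,
    profile_mean,
    relative_net_transitions,
    timelocked_counts,
    timelocked_proportions,
    transition_matrix,
    transitions_table,
)
from gazeshelf.epochs import ROI_LABELS


def fixation_table(records):
    cols = ["subject", "trial", "trial_type", "onset", "end", "row", "col",
            "occupied", "epoch_kind", "grasp_index", "roi"]
    df = pd.DataFrame(records, columns=cols)
    df["duration"] = df.end - df.onset
    return df


def one_grasp_table(onset=5.0, end=6.0):
    return pd.DataFrame([{
        "subject": 0, "trial": 0, "trial_type": "EASY", "grasp_index": 0,
        "onset": onset, "end": end,
        "pickup_row": 3, "pickup_col": 3, "dropoff_row": 1, "dropoff_col": 1,
    }])


class TestTimeLocked:
    def test_single_spanning_fixation_fills_every_bin(self):
        fx = fixation_table([
            (0, 0, "EASY", 0.0, 10.0, 3, 3, True, "preparation", 0, None),
        ])
        counts = timelocked_counts(fx, one_grasp_table())
        props = timelocked_proportions(counts, "subject")
        # the pickup cell is the current target object for this grasp
        assert set(props.roi) == {"cur_target_object"}
        assert sorted(props.bin) == list(range(N_BINS))
        assert (props.proportion == 1.0).all()

    def test_alternating_rois_split_evenly(self):
        # two fixations per bin, one on the target object, one elsewhere
        recs = []
        for b in range(N_BINS):
            t0 = 2.0 + b * 0.25
            recs.append((0, 0, "EASY", t0, t0 + 0.12, 3, 3, True, "preparation", 0, None))
            recs.append((0, 0, "EASY", t0 + 0.125, t0 + 0.245, 5, 5, True, "preparation", 0, None))
        counts = timelocked_counts(fixation_table(recs), one_grasp_table())
        props = timelocked_proportions(counts, "subject")
        assert np.allclose(props.proportion, 0.5)

    def test_bin_proportions_sum_to_one(self, processed):
        counts = timelocked_counts(
            processed["fixations"].head(4000), processed["grasps"]
        )
        props = timelocked_proportions(counts, "subject")
        sums = props.groupby(["subject", "trial_type", "bin"]).proportion.sum()
        assert np.allclose(sums, 1.0)

    def test_target_object_peaks_at_grasp_onset(self, processed):
        """Just-in-time schedule: the current-target proportion is maximal
        in the bin straddling t = 0."""
        counts = timelocked_counts(processed["fixations"], processed["grasps"])
        prof = profile_mean(timelocked_proportions(counts, "subject"))
        onset_bin = int(-(-3.0) / 0.25)   # bin starting at t = 0
        for ttype in ("EASY", "HARD"):
            cur = prof[(prof.roi == "cur_target_object") & (prof.trial_type == ttype)]
            peak = cur.loc[cur["mean"].idxmax()]
            assert cur[cur.bin == onset_bin]["mean"].iloc[0] >= 0.98 * peak["mean"]


class TestClusterPermutation:
    @staticmethod
    def trial_props(n_subjects=6, n_trials=8, effect_bins=(), effect=0.0, seed=0):
        """Synthetic per-trial binned proportions for one ROI pair."""
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subjects):
            for tr in range(n_trials):
                ttype = "EASY" if tr % 2 == 0 else "HARD"
                base = 0.5 + 0.05 * rng.standard_normal(N_BINS)
                if ttype == "EASY":
                    for b in effect_bins:
                        base[b] += effect
                base = np.clip(base, 0.01, 0.99)
                for b in range(N_BINS):
                    rows.append({"subject": s, "trial": s * 100 + tr, "trial_type": ttype,
                                 "bin": b, "roi": "cur_target_object", "proportion": base[b]})
                    rows.append({"subject": s, "trial": s * 100 + tr, "trial_type": ttype,
                                 "bin": b, "roi": "other_objects", "proportion": 1 - base[b]})
        return pd.DataFrame(rows)

    def test_identical_conditions_give_no_significant_clusters(self):
        props = self.trial_props()
        res = cluster_permutation_test(props, "cur_target_object",
                                       n_permutations=300, rng=np.random.default_rng(1))
        assert not res.significant

    def test_injected_offset_is_detected(self):
        props = self.trial_props(effect_bins=range(6, 14), effect=0.2, seed=2)
        res = cluster_permutation_test(props, "cur_target_object",
                                       n_permutations=300, rng=np.random.default_rng(1))
        assert res.significant
        cl = max(res.significant, key=lambda c: abs(c["mass"]))
        assert cl["start"] <= 7 and cl["end"] >= 12

    def test_reproducible_and_subject_order_invariant(self):
        props = self.trial_props(effect_bins=range(8, 12), effect=0.1, seed=3)
        shuffled = props.sample(frac=1.0, random_state=0)
        a = cluster_permutation_test(props, "cur_target_object",
                                     n_permutations=200, rng=np.random.default_rng(5))
        b = cluster_permutation_test(shuffled, "cur_target_object",
                                     n_permutations=200, rng=np.random.default_rng(5))
        assert [c["p"] for c in a.clusters] == [c["p"] for c in b.clusters]

    def test_single_subject_raises(self):
        props = self.trial_props(n_subjects=1)
        with pytest.raises(ValueError):
            cluster_permutation_test(props, "cur_target_object", n_permutations=10)


class TestTransitions:
    def test_forward_chain_has_unit_relative_net(self):
        m = transition_matrix(ROI_LABELS[:4])       # A -> B -> C -> D
        assert m.sum() == 3
        assert relative_net_transitions(m) == 1.0

    def test_hand_enumerated_alternation(self):
        # A B A B: A->B twice, B->A once; R = |2-1| / (2+1)
        a, b = ROI_LABELS[0], ROI_LABELS[1]
        m = transition_matrix([a, b, a, b])
        assert m[0, 1] == 2 and m[1, 0] == 1
        assert relative_net_transitions(m) == pytest.approx(1 / 3)

    def test_long_alternation_tends_to_zero(self):
        a, b = ROI_LABELS[0], ROI_LABELS[1]
        m = transition_matrix([a, b] * 200)
        assert relative_net_transitions(m) == pytest.approx(0.0, abs=0.01)

    def test_refixations_ignored(self):
        a = ROI_LABELS[0]
        m = transition_matrix([a, a, a])
        assert m.sum() == 0
        assert np.isnan(relative_net_transitions(m))
        assert np.all(np.diag(transition_matrix(list(ROI_LABELS))) == 0)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(500):
            m = rng.integers(0, 6, size=(8, 8))
            np.fill_diagonal(m, 0)
            if (m + m.T).sum() == 0:
                continue
            brute = sum(
                abs(int(m[i, j]) - int(m[j, i])) for i in range(8) for j in range(i + 1, 8)
            ) / sum(
                int(m[i, j]) + int(m[j, i]) for i in range(8) for j in range(i + 1, 8)
            )
            assert relative_net_transitions(m) == pytest.approx(brute)

    def test_cohort_values_in_unit_interval(self, processed):
        tab = transitions_table(processed["fixations"])
        assert len(tab) > 50
        assert tab.relative_net_transitions.between(0, 1).all()


class TestLatencies:
    @staticmethod
    def epoch_frame():
        return pd.DataFrame([{
            "subject": 0, "trial": 0, "trial_type": "EASY",
            "epoch_kind": "preparation", "grasp_index": 0,
            "start": 10.0, "end": 14.0, "duration": 4.0,
        }])

    def test_fixation_at_epoch_start_has_zero_latency(self):
        fx = fixation_table([(0, 0, "EASY", 10.0, 10.4, 3, 3, True, "preparation", 0, "cur_target_object")])
        out = first_fixation_latencies(self.epoch_frame(), fx)
        assert out.latency.iloc[0] == 0.0

    def test_fixation_at_midpoint_has_half_latency(self):
        fx = fixation_table([(0, 0, "EASY", 12.0, 12.4, 3, 3, True, "preparation", 0, "cur_target_object")])
        out = first_fixation_latencies(self.epoch_frame(), fx)
        assert out.latency.iloc[0] == pytest.approx(0.5)

    def test_unfixated_roi_is_missing_not_zero(self):
        fx = fixation_table([(0, 0, "EASY", 12.0, 12.4, 3, 3, True, "preparation", 0, "cur_target_object")])
        out = first_fixation_latencies(self.epoch_frame(), fx)
        assert set(out.roi) == {"cur_target_object"}

    def test_latencies_bounded_and_target_lock_fraction_recovered(self, noisy_cohort, processed):
        cfg, _ = noisy_cohort
        out = first_fixation_latencies(processed["epochs"], processed["fixations"])
        assert out.latency.between(0, 1).all()
        for ttype in ("EASY", "HARD"):
            cur = out[(out.roi == "cur_target_object") & (out.trial_type == ttype)
                      & (out.epoch_kind == "preparation")]
            assert cur.latency.mean() == pytest.approx(
                cfg.first_target_fraction[ttype], abs=0.06
            )
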