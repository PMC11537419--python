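"""Grasp extraction, trial QC, epoch segmentation, ROI labeling."""

import numpy as np
import pandas as pd
import pytest

from gazeshelf.epochs import (
    GraspEvent,
    extract_grasps,
    label_fixation,
    qc_trials,
    segment_epochs,
)
from gazeshelf.shelf import ShelfGeometry

GEOM = ShelfGeometry()


def controller_stream(grasp_plan, rate=120.0, t_end=10.0):
    """Build controller arrays from [(t_press, t_release, pick, drop)]."""
    n = int(t_end * rate)
    t = np.arange(n) / rate
    trig = np.zeros(n, dtype=bool)
    pos = np.tile(np.array([0.0, -0.6, 0.6]), (n, 1))
    for t0, t1, pick, drop in grasp_plan:
        sel = (t >= t0) & (t < t1)
        trig |= sel
        i0, i1 = np.searchsorted(t, [t0, t1])
        pos[i0:i1] = np.linspace(GEOM.cell_center(pick), GEOM.cell_center(drop), max(i1 - i0, 1))
        if i1 < n:
            pos[i1] = GEOM.cell_center(drop)
    return t, trig, pos


class TestExtractGrasps:
    def test_single_grasp(self):
        t, trig, pos = controller_stream([(2.0, 3.0, (1, 1), (1, 2))])
        grasps, report = extract_grasps(t, trig, pos, GEOM)
        assert len(grasps) == 1
        g = grasps[0]
        assert g.grasp_index == 0
        assert g.pickup_cell == (1, 1) and g.dropoff_cell == (1, 2)
        assert g.onset == pytest.approx(2.0, abs=1 / 120)

    def test_same_cell_grasp_discarded(self):
        t, trig, pos = controller_stream([(2.0, 3.0, (4, 4), (4, 4)), (5.0, 6.0, (1, 1), (2, 2))])
        grasps, report = extract_grasps(t, trig, pos, GEOM)
        assert len(grasps) == 1 and report["n_same_cell"] == 1
        assert grasps[0].grasp_index == 0   # indices are contiguous after discarding

    def test_unpaired_press_discarded_with_warning(self):
        t, trig, pos = controller_stream([(2.0, 3.0, (1, 1), (1, 2))])
        trig[t >= 8.0] = True   # press without release
        with pytest.warns(UserWarning, match="unpaired"):
            grasps, report = extract_grasps(t, trig, pos, GEOM)
        assert len(grasps) == 1 and report["unpaired_press"]

    def test_implausible_position_flags_trial(self):
        t, trig, pos = controller_stream([(2.0, 3.0, (1, 1), (1, 2))])
        pos[t >= 2.0] += 5.0
        _, report = extract_grasps(t, trig, pos, GEOM)
        assert report["implausible"]


class TestTrialQC:
    @staticmethod
    def table(counts, trial_type="EASY"):
        return pd.DataFrame({
            "subject": 0, "trial": range(len(counts)),
            "trial_type": trial_type, "n_grasps": counts,
        })

    def test_too_few_grasps_removed(self):
        retained, removed = qc_trials(self.table([2, 10, 10, 10]))
        assert set(removed.trial) == {0}
        assert removed.reason.iloc[0] == "too_few_grasps"

    def test_tukey_fence_removes_outlier(self):
        retained, removed = qc_trials(self.table([10, 10, 10, 11, 12, 40]))
        assert set(removed.trial) == {5}
        assert removed.reason.iloc[0] == "outlier_grasp_count"

    def test_homogeneous_counts_untouched(self):
        retained, removed = qc_trials(self.table([10] * 6))
        assert removed.empty and len(retained) == 6

    def test_fence_is_computed_per_trial_type(self):
        tab = pd.concat([self.table([10] * 5, "EASY"), self.table([20] * 5, "HARD")])
        tab["trial"] = range(len(tab))
        retained, removed = qc_trials(tab)
        assert removed.empty   # 20 is normal for HARD

    def test_deterministic(self):
        tab = self.table([3, 5, 8, 9, 30, 10])
        a = qc_trials(tab)[0]
        b = qc_trials(tab)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_everything_removed_raises(self):
        with pytest.raises(ValueError):
            qc_trials(self.table([1, 2, 2]))


class TestSegmentEpochs:
    G = [
        GraspEvent(2.0, 3.0, (1, 1), (1, 2), 0),
        GraspEvent(4.0, 5.0, (2, 2), (2, 3), 1),
        GraspEvent(6.5, 7.0, (3, 3), (3, 4), 2),
    ]

    def test_three_grasps_make_six_epochs(self):
        eps = segment_epochs(self.G, trial_start=0.0)
        assert len(eps) == 6
        kinds = [e.kind for e in eps]
        assert kinds == ["preparation", "execution"] * 3

    def test_boundaries_tile_the_timeline(self):
        eps = segment_epochs(self.G, trial_start=0.0)
        assert eps[0].start == 0.0 and eps[0].end == 2.0          # first preparation
        assert eps[1].start == 2.0 and eps[1].end == 3.0          # first execution
        assert eps[2].start == 3.0 and eps[2].end == 4.0          # prep = prev end..onset
        for a, b in zip(eps[:-1], eps[1:]):
            assert a.end == b.start

    def test_zero_length_preparation_dropped(self):
        grasps = [GraspEvent(1.0, 2.0, (1, 1), (1, 2), 0),
                  GraspEvent(2.0, 3.0, (2, 2), (2, 3), 1)]
        with pytest.warns(UserWarning, match="zero-length"):
            eps = segment_epochs(grasps, trial_start=0.0)
        assert sum(e.kind == "preparation" for e in eps) == 1

    def test_overlapping_grasps_raise(self):
        grasps = [GraspEvent(1.0, 3.0, (1, 1), (1, 2), 0),
                  GraspEvent(2.5, 4.0, (2, 2), (2, 3), 1)]
        with pytest.raises(ValueError, match="overlap"):
            segment_epochs(grasps, trial_start=0.0)


class TestRoiLabels:
    G = [
        GraspEvent(1.0, 2.0, (1, 1), (2, 2), 0),   # previous
        GraspEvent(3.0, 4.0, (3, 3), (4, 4), 1),   # current (reference)
        GraspEvent(5.0, 6.0, (5, 5), (1, 5), 2),   # next
    ]

    @pytest.mark.parametrize(
        "cell, occupied, expected",
        [
            ((3, 3), True, "cur_target_object"),
            ((4, 4), False, "cur_target_shelf"),
            ((5, 5), True, "next_target_object"),
            ((1, 5), False, "next_target_shelf"),
            ((2, 2), True, "prev_target_object"),
            ((2, 2), False, "prev_target_shelf"),
            ((1, 2), True, "other_objects"),
            ((1, 2), False, "other_shelves"),
            ((1, 1), False, "other_shelves"),       # previous *pickup* is not a target
        ],
    )
    def test_labels(self, cell, occupied, expected):
        assert label_fixation(cell, occupied, self.G, 1) == expected

    def test_outside_shelf_is_unlabeled(self):
        assert label_fixation(None, False, self.G, 1) is None

    def test_precedence_current_over_previous(self):
        # previous drop-off coincides with the current pickup
        grasps = [
            GraspEvent(1.0, 2.0, (1, 1), (3, 3), 0),
            GraspEvent(3.0, 4.0, (3, 3), (4, 4), 1),
        ]
        assert label_fixation((3, 3), True, grasps, 1) == "cur_target_object"

    def test_first_and_last_grasp_have_no_prev_next(self):
        # reference 0: no previous targets exist, unrelated cells are other
        assert label_fixation((1, 3), True, self.G, 0) == "other_objects"
        # reference 2 (last): cells of a hypothetical next action are just other
        assert label_fixation((3, 3), False, self.G, 2) == "other_shelves"
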