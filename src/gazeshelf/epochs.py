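"""Grasp extraction, trial quality control, epoch segmentation and
action-relative ROI labeling.

A grasp (object displacement) is delimited by the controller trigger:
press marks the pickup, release the drop-off; the pickup/drop-off cells
are the shelf cells nearest the controller position at those instants.
Each grasp induces two epochs: the *preparation* epoch runs from the end
of the previous grasp (or trial start) to the current grasp onset, the
*execution* epoch from grasp onset to grasp end.

Every fixation is labeled with one of eight action-relative regions of
interest (ROIs) with respect to a reference grasp:

===================  =====================================================
cur_target_object    cell the current grasp picks up from
cur_target_shelf     cell the current grasp drops off at
next_target_object   pickup cell of the following grasp
next_target_shelf    drop-off cell of the following grasp
prev_target_object   drop-off cell of the previous grasp, while the
                     displaced object still occupies it
prev_target_shelf    the same cell once it no longer holds the object
other_objects        any other occupied cell
other_shelves        any other empty cell
===================  =====================================================

The previous action's target object and target shelf are spatially
identical (the object sits where it was just placed), so the two previous
labels are distinguished by occupancy.  When cells coincide across the
previous/current/next grasps, precedence is current > next > previous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .shelf import Cell, Move, ShelfGeometry, ShelfState

ROI_LABELS = (
    "prev_target_object",
    "prev_target_shelf",
    "cur_target_object",
    "cur_target_shelf",
    "next_target_object",
    "next_target_shelf",
    "other_objects",
    "other_shelves",
)


@dataclass
class GraspEvent:
    """One pickup-move-release of a shelf object."""

    onset: float         # trigger press, s
    end: float           # trigger release, s
    pickup_cell: Cell
    dropoff_cell: Cell
    grasp_index: int     # 0-based order within the trial

    def __post_init__(self) -> None:
        if self.onset >= self.end:
            raise ValueError("grasp onset must precede its end")


@dataclass
class Epoch:
    """Preparation or execution interval tied to one grasp."""

    kind: str            # "preparation" | "execution"
    start: float
    end: float
    grasp_index: int

    @property
    def duration(self) -> float:
        return self.end - self.start


def extract_grasps(
    t: np.ndarray,
    trigger: np.ndarray,
    position: np.ndarray,
    geometry: ShelfGeometry = ShelfGeometry(),
    position_tolerance: float = 0.5,
) -> tuple[list[GraspEvent], dict]:
    """Extract grasp events from a controller stream.

    Press/release instants are the first samples where the boolean trigger
    turns on/off; pickup and drop-off cells are the shelf cells nearest
    the controller position at those instants.  Grasps whose pickup and
    drop-off cells coincide are discarded.  Controller positions farther
    than ``position_tolerance`` meters from every cell center flag the
    trial as implausible (report key ``implausible``); an unpaired press
    at the end of the stream is discarded with a warning.
    """
    t = np.asarray(t, dtype=float)
    trig = np.asarray(trigger, dtype=bool)
    pos = np.asarray(position, dtype=float)
    edges = np.diff(trig.astype(int))
    presses = list(np.where(edges == 1)[0] + 1)
    releases = list(np.where(edges == -1)[0] + 1)
    if trig.size and trig[0]:
        presses.insert(0, 0)

    grasps: list[GraspEvent] = []
    report = {"n_pairs": 0, "n_same_cell": 0, "implausible": False, "unpaired_press": False}
    idx = 0
    for p in presses:
        r = next((r for r in releases if r > p), None)
        if r is None:
            report["unpaired_press"] = True
            warnings.warn("unpaired trigger press at end of stream; grasp discarded")
            break
        report["n_pairs"] += 1
        pick, d_pick = geometry.nearest_cell_to_position(pos[p])
        drop, d_drop = geometry.nearest_cell_to_position(pos[r])
        if d_pick > position_tolerance or d_drop > position_tolerance:
            report["implausible"] = True
        if pick == drop:
            report["n_same_cell"] += 1
            continue
        grasps.append(GraspEvent(float(t[p]), float(t[r]), pick, drop, idx))
        idx += 1
    return grasps, report


def qc_trials(
    trial_table: pd.DataFrame,
    min_grasps: int = 3,
    iqr_factor: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trial-level quality control on grasp counts.

    ``trial_table`` needs columns ``subject, trial, trial_type, n_grasps``
    (one row per trial).  Trials with fewer than ``min_grasps`` grasps are
    removed, as are trials whose grasp count exceeds the upper Tukey fence
    Q3 + ``iqr_factor`` * IQR of the per-trial-type count distribution.
    Returns ``(retained trials, report of removals with reasons)``.

    Raises
    ------
    ValueError
        If no trial survives.
    """
    required = {"subject", "trial", "trial_type", "n_grasps"}
    if not required.issubset(trial_table.columns):
        raise ValueError(f"trial_table must have columns {sorted(required)}")
    tab = trial_table.copy()
    reasons = pd.Series("", index=tab.index, dtype=object)
    reasons[tab.n_grasps < min_grasps] = "too_few_grasps"
    for ttype, grp in tab.groupby("trial_type"):
        q1, q3 = np.percentile(grp.n_grasps, [25, 75])
        fence = q3 + iqr_factor * (q3 - q1)
        over = grp.index[grp.n_grasps > fence]
        for i in over:
            if not reasons[i]:
                reasons[i] = "outlier_grasp_count"
    removed = tab[reasons != ""].assign(reason=reasons[reasons != ""])
    retained = tab[reasons == ""]
    if retained.empty:
        raise ValueError("quality control removed every trial")
    return retained.reset_index(drop=True), removed.reset_index(drop=True)


def segment_epochs(
    grasps: Sequence[GraspEvent], trial_start: float
) -> list[Epoch]:
    """Tile the grasping timeline into preparation and execution epochs.

    Preparation of grasp k spans ``[end(k-1), onset(k))`` (``[trial_start,
    onset(0))`` for the first grasp); execution spans ``[onset(k),
    end(k)]``.  Zero-length preparation epochs (consecutive grasps with no
    gap) are dropped with a warning.

    Raises
    ------
    ValueError
        On temporally overlapping grasps (indices named).
    """
    epochs: list[Epoch] = []
    prev_end = trial_start
    for i, g in enumerate(grasps):
        if g.onset < prev_end - 1e-12 and i > 0:
            raise ValueError(f"grasps {i - 1} and {i} overlap")
        if g.onset > prev_end:
            epochs.append(Epoch("preparation", prev_end, g.onset, g.grasp_index))
        else:
            warnings.warn(f"zero-length preparation epoch before grasp {g.grasp_index}; dropped")
        epochs.append(Epoch("execution", g.onset, g.end, g.grasp_index))
        prev_end = g.end
    return epochs


def fixation_cell(
    mean_dir: np.ndarray, geometry: ShelfGeometry = ShelfGeometry()
) -> Optional[Cell]:
    """Shelf cell a fixation lands on, or None when the gaze direction is
    farther than half the cell pitch from every cell center."""
    cell, ang = geometry.nearest_cell_to_direction(mean_dir)
    if ang > geometry.cell_pitch_deg / 2:
        return None
    return cell


def state_before_grasp(initial_state: ShelfState, grasps: Sequence[GraspEvent], k: int) -> ShelfState:
    """Shelf state at the start of grasp ``k``'s preparation epoch (moves
    0..k-1 applied)."""
    state = initial_state
    for g in grasps[:k]:
        state = state.apply(Move(g.pickup_cell, g.dropoff_cell))
    return state


def label_fixation(
    cell: Optional[Cell],
    occupied: bool,
    grasps: Sequence[GraspEvent],
    reference_index: int,
) -> Optional[str]:
    """Action-relative ROI label of a fixated cell w.r.t. a reference grasp.

    ``occupied`` is the cell's occupancy at fixation time.  Returns None
    when the fixation is outside the shelf (``cell is None``); such
    fixations are excluded from ROI analyses.  The first grasp of a trial
    has no previous targets and the last no next targets; those cells fall
    through to the ``other_*`` categories.
    """
    if cell is None:
        return None
    cur = grasps[reference_index]
    if cell == cur.pickup_cell:
        return "cur_target_object"
    if cell == cur.dropoff_cell:
        return "cur_target_shelf"
    if reference_index + 1 < len(grasps):
        nxt = grasps[reference_index + 1]
        if cell == nxt.pickup_cell:
            return "next_target_object"
        if cell == nxt.dropoff_cell:
            return "next_target_shelf"
    if reference_index > 0:
        prev = grasps[reference_index - 1]
        if cell == prev.dropoff_cell:
            return "prev_target_object" if occupied else "prev_target_shelf"
    return "other_objects" if occupied else "other_shelves"
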