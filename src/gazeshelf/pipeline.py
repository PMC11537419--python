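"""End-to-end processing of recorded (or simulated) sessions into tidy
analysis tables.

``process_sessions`` runs, per trial: fixation detection on the gaze
stream, grasp extraction from the controller stream, trial-level quality
control on grasp counts, epoch segmentation, and action-relative ROI
labeling of every fixation.  The result is a dict of pandas DataFrames
(``trials``, ``grasps``, ``epochs``, ``fixations``) shared by all
downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .epochs import (
    GraspEvent,
    extract_grasps,
    fixation_cell,
    label_fixation,
    qc_trials,
    segment_epochs,
    state_before_grasp,
)
from .preprocess import SaccadeDetectionParams, detect_fixations
from .shelf import ShelfGeometry
from .synth import SessionRecording, TrialRecording


def process_trial(
    trial: TrialRecording,
    params: SaccadeDetectionParams = SaccadeDetectionParams(),
    geometry: Optional[ShelfGeometry] = None,
    apply_duration_filter: bool = True,
) -> dict:
    """Process one trial's raw streams.

    Returns a dict with detected ``fixations`` (incl. cell and ROI),
    ``grasps``, ``epochs`` DataFrames and a ``report``.
    """
    geom = geometry or ShelfGeometry()
    fixations, report = detect_fixations(
        trial.t_gaze, trial.gaze_dir, params, apply_duration_filter=apply_duration_filter
    )
    grasps, grasp_report = extract_grasps(trial.t_ctrl, trial.trigger, trial.ctrl_pos, geom)
    report["grasps"] = grasp_report
    epochs = segment_epochs(grasps, trial.trial_start) if grasps else []

    # fixation -> epoch attribution by onset; ROI label w.r.t. that epoch's grasp
    fix_rows = []
    states = {}
    for fx in fixations:
        cell = fixation_cell(fx.mean_dir, geom) if fx.mean_dir is not None else None
        epoch = next(
            (ep for ep in epochs if ep.start <= fx.onset < ep.end), None
        )
        roi = None
        occupied = False
        if epoch is not None and cell is not None:
            k = epoch.grasp_index
            if k not in states:
                states[k] = state_before_grasp(trial.initial_state, grasps, k)
            occupied = states[k][cell] is not None
            roi = label_fixation(cell, occupied, grasps, k)
        fix_rows.append({
            "onset": fx.onset, "end": fx.end, "duration": fx.duration,
            "row": cell[0] if cell else np.nan, "col": cell[1] if cell else np.nan,
            "occupied": occupied,
            "epoch_kind": epoch.kind if epoch else None,
            "grasp_index": epoch.grasp_index if epoch else np.nan,
            "roi": roi,
        })
    return {
        "fixations": pd.DataFrame(fix_rows),
        "grasps": grasps,
        "epochs": epochs,
        "report": report,
    }


def process_sessions(
    sessions: Sequence[SessionRecording],
    params: SaccadeDetectionParams = SaccadeDetectionParams(),
    geometry: Optional[ShelfGeometry] = None,
    apply_qc: bool = True,
) -> dict[str, pd.DataFrame]:
    """Process whole sessions into tidy tables.

    Returns dict with keys:

    ``trials``
        subject, trial, instruction_id, trial_type, n_grasps,
        trial_duration, retained (QC flag)
    ``grasps``
        one row per grasp of retained trials
    ``epochs``
        one row per epoch of retained trials
    ``fixations``
        one row per detected fixation of retained trials, with cell, ROI
        and epoch attribution
    ``qc_removed``
        QC report of removed trials
    """
    trial_rows, grasp_rows, epoch_rows, fix_frames = [], [], [], []
    per_trial: dict[tuple[int, int], dict] = {}
    for sess in sessions:
        for tr in sess.trials:
            out = process_trial(tr, params, geometry)
            per_trial[(tr.subject, tr.trial)] = out
            grasps = out["grasps"]
            duration = (grasps[-1].end - tr.trial_start) if grasps else 0.0
            trial_rows.append({
                "subject": tr.subject, "trial": tr.trial,
                "instruction_id": tr.instruction.id, "trial_type": tr.trial_type,
                "n_grasps": len(grasps), "trial_duration": duration,
            })
    trials = pd.DataFrame(trial_rows)
    if apply_qc:
        retained, removed = qc_trials(trials)
        keys = set(zip(retained.subject, retained.trial))
    else:
        removed = trials.iloc[0:0].assign(reason=pd.Series(dtype=object))
        keys = set(zip(trials.subject, trials.trial))
    trials["retained"] = [
        (s, t) in keys for s, t in zip(trials.subject, trials.trial)
    ]

    for (s, t), out in per_trial.items():
        if (s, t) not in keys:
            continue
        meta = trials[(trials.subject == s) & (trials.trial == t)].iloc[0]
        for g in out["grasps"]:
            grasp_rows.append({
                "subject": s, "trial": t, "trial_type": meta.trial_type,
                "grasp_index": g.grasp_index, "onset": g.onset, "end": g.end,
                "pickup_row": g.pickup_cell[0], "pickup_col": g.pickup_cell[1],
                "dropoff_row": g.dropoff_cell[0], "dropoff_col": g.dropoff_cell[1],
            })
        for ep in out["epochs"]:
            epoch_rows.append({
                "subject": s, "trial": t, "trial_type": meta.trial_type,
                "epoch_kind": ep.kind, "grasp_index": ep.grasp_index,
                "start": ep.start, "end": ep.end, "duration": ep.duration,
            })
        fx = out["fixations"].copy()
        fx.insert(0, "subject", s)
        fx.insert(1, "trial", t)
        fx.insert(2, "trial_type", meta.trial_type)
        fix_frames.append(fx)

    return {
        "trials": trials,
        "grasps": pd.DataFrame(grasp_rows),
        "epochs": pd.DataFrame(epoch_rows),
        "fixations": (
            pd.concat(fix_frames, ignore_index=True) if fix_frames else pd.DataFrame()
        ),
        "qc_removed": removed,
    }


def truth_tables(sessions: Sequence[SessionRecording]) -> dict[str, pd.DataFrame]:
    """Ground-truth grasp/epoch/fixation tables of simulated sessions, in
    the same layout as :func:`process_sessions` output (no QC applied)."""
    grasp_rows, epoch_rows, fix_frames = [], [], []
    for sess in sessions:
        for tr in sess.trials:
            for g in tr.truth_grasps:
                grasp_rows.append({
                    "subject": tr.subject, "trial": tr.trial, "trial_type": tr.trial_type,
                    "grasp_index": g.grasp_index, "onset": g.onset, "end": g.end,
                    "pickup_row": g.pickup_cell[0], "pickup_col": g.pickup_cell[1],
                    "dropoff_row": g.dropoff_cell[0], "dropoff_col": g.dropoff_cell[1],
                })
            for ep in tr.truth_epochs:
                epoch_rows.append({
                    "subject": tr.subject, "trial": tr.trial, "trial_type": tr.trial_type,
                    "epoch_kind": ep.kind, "grasp_index": ep.grasp_index,
                    "start": ep.start, "end": ep.end, "duration": ep.duration,
                })
            fx = tr.truth_fixations.copy()
            if len(fx):
                fx.insert(0, "subject", tr.subject)
                fx.insert(1, "trial", tr.trial)
                fx.insert(2, "trial_type", tr.trial_type)
                fix_frames.append(fx)
    return {
        "grasps": pd.DataFrame(grasp_rows),
        "epochs": pd.DataFrame(epoch_rows),
        "fixations": (
            pd.concat(fix_frames, ignore_index=True) if fix_frames else pd.DataFrame()
        ),
    }
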