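"""Behavioral outcome measures: durations, human-vs-model displacement
counts, spatial pickup/drop-off propensities and their correlation with
trial progression.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .solver import greedy_solve
from .synth import SessionRecording


def summarize_durations(epochs: pd.DataFrame, trials: Optional[pd.DataFrame] = None) -> dict:
    """Duration summaries by trial type and epoch type.

    Per-subject means are computed first; the grand mean/SD is taken
    across subjects (matching by-subject dot plots).  If ``trials`` (with
    ``trial_duration``) is given, trial-duration summaries and a
    two-sample t-test on per-subject mean trial durations (EASY vs HARD)
    are included.

    Returns dict with ``per_subject``, ``grand`` and optionally
    ``trial_grand``, ``trial_ttest``.
    """
    if epochs.empty:
        raise ValueError("empty epoch table")
    per_subject = (
        epochs.groupby(["subject", "trial_type", "epoch_kind"])["duration"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    grand = (
        per_subject.groupby(["trial_type", "epoch_kind"])["mean"]
        .agg(grand_mean="mean", grand_sd="std", n_subjects="count")
        .reset_index()
    )
    grand["grand_sd"] = grand["grand_sd"].fillna(0.0)
    out = {"per_subject": per_subject, "grand": grand}
    if trials is not None:
        tt = trials[trials.get("retained", True) == True]  # noqa: E712
        per_subj_trial = (
            tt.groupby(["subject", "trial_type"])["trial_duration"].mean().reset_index()
        )
        out["trial_grand"] = (
            per_subj_trial.groupby("trial_type")["trial_duration"]
            .agg(grand_mean="mean", grand_sd="std", n_subjects="count")
            .reset_index()
        )
        easy = per_subj_trial.query("trial_type == 'EASY'")["trial_duration"]
        hard = per_subj_trial.query("trial_type == 'HARD'")["trial_duration"]
        if len(easy) > 1 and len(hard) > 1:
            t, p = stats.ttest_ind(easy, hard)
            out["trial_ttest"] = {"t": float(t), "p": float(p)}
    return out


def compare_to_model(
    sessions: Sequence[SessionRecording],
    trials: pd.DataFrame,
    grasps: pd.DataFrame,
    method: str = "steepest",
    constrained: bool = False,
) -> pd.DataFrame:
    """Pair each retained trial's human displacement count with the greedy
    model's count on the same initial configuration.

    ``method="steepest"`` counts the model's trajectory length (an agent
    replaying the model makes exactly this many displacements);
    ``method="stack"`` reports the stack-based search's explored-state
    count instead.

    Returns a long table with one HUMAN and one MODEL row per trial
    (columns subject, trial, trial_type, solver_type, n_moves).  Trials
    the model cannot solve are excluded and counted in the table's
    ``attrs['n_model_unsolved']``.
    """
    by_key = {(s.subject, tr.trial): tr for s in sessions for tr in s.trials}
    counts = grasps.groupby(["subject", "trial"]).size()
    rows = []
    unsolved = 0
    retained = trials[trials.get("retained", True) == True]  # noqa: E712
    for _, meta in retained.iterrows():
        key = (meta.subject, meta.trial)
        tr = by_key.get(key)
        if tr is None or key not in counts.index:
            continue
        res = greedy_solve(tr.initial_state, tr.instruction, constrained=constrained, method=method)
        if not res.solved:
            unsolved += 1
            continue
        for solver_type, n in (("HUMAN", int(counts[key])), ("MODEL", res.n_moves)):
            rows.append({
                "subject": meta.subject, "trial": meta.trial,
                "trial_type": meta.trial_type, "solver_type": solver_type,
                "n_moves": n,
            })
    out = pd.DataFrame(rows)
    out.attrs["n_model_unsolved"] = unsolved
    return out


def propensity_maps(grasps: pd.DataFrame, n_rows: int = 5, n_cols: int = 5) -> dict:
    """Pickup and drop-off location probability maps per trial type.

    Returns ``{(event, trial_type): (n_rows x n_cols) array}``; each map's
    entries are counts normalized by the total number of displacements of
    that trial type, so they sum to 1.
    """
    if grasps.empty:
        raise ValueError("no grasps")
    maps = {}
    for ttype, grp in grasps.groupby("trial_type"):
        for event, (rcol, ccol) in (
            ("pickup", ("pickup_row", "pickup_col")),
            ("dropoff", ("dropoff_row", "dropoff_col")),
        ):
            m = np.zeros((n_rows, n_cols))
            for r, c in zip(grp[rcol], grp[ccol]):
                m[int(r) - 1, int(c) - 1] += 1
            maps[(event, ttype)] = m / m.sum()
    return maps


def grasp_index_correlations(grasps: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation between mean pickup/drop-off row/column and
    grasp index.

    Following the by-subject presentation of the spatial-progression
    analysis, the mean location per (subject, grasp index) is computed
    first and the rank correlation taken across those subject-index
    pairs, separately per trial type.  Undefined correlations (constant
    values) are reported as NaN.
    """
    rows = []
    for ttype, grp in grasps.groupby("trial_type"):
        for event, (rcol, ccol) in (
            ("pickup", ("pickup_row", "pickup_col")),
            ("dropoff", ("dropoff_row", "dropoff_col")),
        ):
            agg = grp.groupby(["subject", "grasp_index"])[[rcol, ccol]].mean().reset_index()
            for axis, col in (("row", rcol), ("column", ccol)):
                vals = agg[col].to_numpy()
                idx = agg["grasp_index"].to_numpy()
                if len(np.unique(idx)) < 3 or np.all(vals == vals[0]):
                    rho, p = np.nan, np.nan
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        rho, p = stats.spearmanr(vals, idx)
                rows.append({
                    "trial_type": ttype, "event": event, "axis": axis,
                    "rho": float(rho) if rho == rho else np.nan,
                    "p": float(p) if p == p else np.nan,
                    "n": len(agg),
                })
    return pd.DataFrame(rows)
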