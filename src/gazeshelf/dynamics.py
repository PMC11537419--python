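"""Action-locked gaze dynamics: time-locked fixation proportions with
cluster-based permutation testing, ROI transition matrices with relative
net transitions, and normalized first-fixation latencies.

Time-locked profiles count, in 0.25 s bins spanning 3 s before to 2 s
after each grasp onset, the fixations on each of the eight
action-relative ROIs (labels are re-derived relative to *each* reference
grasp, so a fixation can be ``next_target_object`` for one grasp and
``cur_target_object`` for the following one).  A fixation contributes to
every bin it overlaps; per subject and bin the ROI counts are normalized
to proportions, which are then averaged across subjects.

Condition differences are assessed per ROI with a cluster-based
permutation test on the per-bin t statistic ``t = sqrt(N) * mean(d) /
sd(d)`` over the per-subject EASY-HARD proportion differences d.
Contiguous bins with |t| above a fixed threshold (default 2.14) form
clusters whose mass is the sum of their t values; the null distribution
of the maximal absolute cluster mass is obtained by shuffling the time-bin
labels within every trial's binned series.  With eight ROIs tested, the
per-cluster significance level is Bonferroni-corrected to 0.05/8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .epochs import ROI_LABELS, label_fixation

WINDOW = (-3.0, 2.0)
BIN_WIDTH = 0.25
N_BINS = int(round((WINDOW[1] - WINDOW[0]) / BIN_WIDTH))


# ---------------------------------------------------------------------------
# Time-locked fixation proportions

def timelocked_counts(
    fixations: pd.DataFrame,
    grasps: pd.DataFrame,
    window: tuple[float, float] = WINDOW,
    bin_width: float = BIN_WIDTH,
    assignment: str = "overlap",
) -> pd.DataFrame:
    """Per-(grasp, bin, ROI) fixation counts around every grasp onset.

    ``fixations`` needs columns subject, trial, trial_type, onset, end,
    row, col, occupied; ``grasps`` the pipeline grasp table.  Fixations
    are relabeled relative to each reference grasp.  ``assignment`` is
    ``"overlap"`` (a fixation counts in every bin it overlaps) or
    ``"onset"`` (only the bin containing its onset).

    Returns a long DataFrame: subject, trial, trial_type, grasp_index,
    bin, roi, count.
    """
    n_bins = int(round((window[1] - window[0]) / bin_width))
    rows = []
    from .epochs import GraspEvent  # local to avoid cycle at import time

    for (subj, trial), g_grp in grasps.groupby(["subject", "trial"]):
        g_grp = g_grp.sort_values("grasp_index")
        glist = [
            GraspEvent(r.onset, r.end, (int(r.pickup_row), int(r.pickup_col)),
                       (int(r.dropoff_row), int(r.dropoff_col)), int(r.grasp_index))
            for r in g_grp.itertuples()
        ]
        fx = fixations[(fixations.subject == subj) & (fixations.trial == trial)]
        fx = fx[fx.row.notna()]
        ttype = g_grp.trial_type.iloc[0]
        for k, g in enumerate(glist):
            w0, w1 = g.onset + window[0], g.onset + window[1]
            sel = fx[(fx.end > w0) & (fx.onset < w1)]
            for f in sel.itertuples():
                roi = label_fixation((int(f.row), int(f.col)), bool(f.occupied), glist, k)
                if roi is None:
                    continue
                if assignment == "onset":
                    b = int(np.floor((f.onset - w0) / bin_width))
                    bins = [b] if 0 <= b < n_bins else []
                else:
                    b0 = int(np.floor((max(f.onset, w0) - w0) / bin_width))
                    b1 = int(np.ceil((min(f.end, w1) - w0) / bin_width))
                    bins = range(max(b0, 0), min(b1, n_bins))
                for b in bins:
                    rows.append({
                        "subject": subj, "trial": trial, "trial_type": ttype,
                        "grasp_index": k, "bin": b, "roi": roi,
                    })
    if not rows:
        return pd.DataFrame(columns=["subject", "trial", "trial_type", "grasp_index", "bin", "roi", "count"])
    out = (
        pd.DataFrame(rows)
        .groupby(["subject", "trial", "trial_type", "grasp_index", "bin", "roi"])
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def timelocked_proportions(counts: pd.DataFrame, level: str = "subject") -> pd.DataFrame:
    """Normalize time-locked counts to ROI proportions.

    ``level="subject"``: counts pooled per (subject, trial_type, bin) then
    normalized over ROIs; the returned profile additionally contains the
    across-subject mean (``level="mean"`` rows are obtained with
    :func:`profile_mean`).  ``level="trial"``: normalized per (trial,
    grasp... ) -- used by the permutation test.
    """
    if level == "subject":
        g = counts.groupby(["subject", "trial_type", "bin", "roi"])["count"].sum().reset_index()
        totals = g.groupby(["subject", "trial_type", "bin"])["count"].transform("sum")
        g["proportion"] = g["count"] / totals
        return g
    if level == "trial":
        g = counts.groupby(["subject", "trial", "trial_type", "bin", "roi"])["count"].sum().reset_index()
        totals = g.groupby(["subject", "trial", "trial_type", "bin"])["count"].transform("sum")
        g["proportion"] = g["count"] / totals
        return g
    raise ValueError(level)


def profile_mean(subject_props: pd.DataFrame) -> pd.DataFrame:
    """Across-subject mean time course per (trial_type, bin, roi)."""
    return (
        subject_props.groupby(["trial_type", "bin", "roi"])["proportion"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Cluster-based permutation test

@dataclass
class ClusterTestResult:
    roi: str
    t: np.ndarray                      # per-bin t statistic (NaN where undefined)
    clusters: list[dict] = field(default_factory=list)   # start, end, mass, p
    threshold: float = 2.14
    alpha: float = 0.006
    n_permutations: int = 1000

    @property
    def significant(self) -> list[dict]:
        return [c for c in self.clusters if c["p"] < self.alpha]


def _trial_bin_matrix(trial_props: pd.DataFrame, roi: str, n_bins: int = N_BINS):
    """Pivot one ROI's per-trial binned proportions into a dense matrix.

    Missing (trial, bin) combinations (no fixations in the bin) are 0 for
    the ROI when the bin had data for other ROIs, else NaN.
    """
    sub = trial_props[["subject", "trial", "trial_type", "bin"]].drop_duplicates()
    wide = sub.set_index(["subject", "trial", "trial_type", "bin"]).assign(proportion=0.0)
    roi_rows = trial_props[trial_props.roi == roi].set_index(
        ["subject", "trial", "trial_type", "bin"]
    )["proportion"]
    wide.loc[roi_rows.index, "proportion"] = roi_rows
    wide = wide.reset_index().pivot_table(
        index=["subject", "trial", "trial_type"], columns="bin", values="proportion"
    ).reindex(columns=range(n_bins))
    subjects = wide.index.get_level_values("subject").to_numpy()
    ttypes = wide.index.get_level_values("trial_type").to_numpy()
    return wide.to_numpy(), subjects, ttypes


def _t_series(mat, subjects, ttypes) -> np.ndarray:
    """Per-bin t over per-subject EASY-HARD proportion differences."""
    subs = np.unique(subjects)
    diffs = np.full((len(subs), mat.shape[1]), np.nan)
    for i, s in enumerate(subs):
        e = mat[(subjects == s) & (ttypes == "EASY")]
        h = mat[(subjects == s) & (ttypes == "HARD")]
        if len(e) and len(h):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                diffs[i] = np.nanmean(e, axis=0) - np.nanmean(h, axis=0)
    n = np.sum(~np.isnan(diffs), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(diffs, axis=0)
        sd = np.nanstd(diffs, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.sqrt(n) * mean / sd
    t[(sd == 0) | (n < 2)] = np.nan
    return t


def _clusters_from_t(t: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    """Sign-consistent contiguous supra-threshold clusters (start, end incl., mass)."""
    out = []
    i = 0
    n = len(t)
    while i < n:
        if np.isnan(t[i]) or abs(t[i]) <= threshold:
            i += 1
            continue
        sign = np.sign(t[i])
        j = i
        while j + 1 < n and not np.isnan(t[j + 1]) and abs(t[j + 1]) > threshold and np.sign(t[j + 1]) == sign:
            j += 1
        out.append((i, j, float(np.sum(t[i:j + 1]))))
        i = j + 1
    return out


def cluster_permutation_core(
    mat: np.ndarray,
    subjects: np.ndarray,
    ttypes: np.ndarray,
    threshold: float = 2.14,
    n_permutations: int = 1000,
    alpha: float = 0.006,
    rng: Optional[np.random.Generator] = None,
    roi: str = "",
) -> ClusterTestResult:
    """Permutation machinery on a dense (n_trials x n_bins) matrix of one
    ROI's per-trial binned proportions (see :func:`cluster_permutation_test`).
    """
    rng = rng or np.random.default_rng(0)
    if len(np.unique(subjects)) < 2:
        raise ValueError("need at least two subjects")
    t_obs = _t_series(mat, subjects, ttypes)
    clusters = _clusters_from_t(t_obs, threshold)

    n_trials, n_bins = mat.shape
    dense = not np.isnan(mat).any()
    if dense:
        # averaging-weight matrices: row s averages subject s's trials of
        # one condition; subjects lacking a condition are excluded
        subs = np.unique(subjects)
        w_e = np.zeros((len(subs), n_trials))
        w_h = np.zeros((len(subs), n_trials))
        for i, s in enumerate(subs):
            e = (subjects == s) & (ttypes == "EASY")
            h = (subjects == s) & (ttypes == "HARD")
            if e.any():
                w_e[i, e] = 1.0 / e.sum()
            if h.any():
                w_h[i, h] = 1.0 / h.sum()
        keep = (w_e.sum(axis=1) > 0) & (w_h.sum(axis=1) > 0)
        w_e, w_h = w_e[keep], w_h[keep]
        n_eff = keep.sum()

    null_max = np.zeros(n_permutations)
    for p in range(n_permutations):
        perm = np.argsort(rng.random((n_trials, n_bins)), axis=1)
        shuffled = np.take_along_axis(mat, perm, axis=1)
        if dense:
            diffs = w_e @ shuffled - w_h @ shuffled
            sd = diffs.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_null = np.sqrt(n_eff) * diffs.mean(axis=0) / sd
            t_null[sd == 0] = np.nan
        else:
            t_null = _t_series(shuffled, subjects, ttypes)
        cl = _clusters_from_t(t_null, threshold)
        null_max[p] = max((abs(m) for *_se, m in cl), default=0.0)

    result = ClusterTestResult(
        roi=roi, t=t_obs, threshold=threshold, alpha=alpha, n_permutations=n_permutations
    )
    for start, end, mass in clusters:
        pval = float(np.mean(null_max >= abs(mass)))
        result.clusters.append({"start": start, "end": end, "mass": mass, "p": pval})
    return result


def cluster_permutation_test(
    trial_props: pd.DataFrame,
    roi: str,
    threshold: float = 2.14,
    n_permutations: int = 1000,
    alpha: float = 0.006,
    rng: Optional[np.random.Generator] = None,
) -> ClusterTestResult:
    """Cluster-based permutation test of EASY vs HARD fixation proportions
    for one ROI.

    ``trial_props`` is the ``level="trial"`` output of
    :func:`timelocked_proportions` (all ROIs; the tested ROI's absent
    bins count as proportion 0).  The null distribution shuffles the
    time-bin labels independently within every trial's binned series and
    records the maximal absolute cluster mass.  A cluster's p-value is
    the fraction of null masses at least as large as its own.
    """
    mat, subjects, ttypes = _trial_bin_matrix(trial_props, roi)
    return cluster_permutation_core(
        mat, subjects, ttypes, threshold, n_permutations, alpha, rng, roi=roi
    )


# ---------------------------------------------------------------------------
# Transition matrices

def transition_matrix(roi_sequence: Sequence[str]) -> np.ndarray:
    """8x8 ROI transition counts of one epoch's fixation sequence.

    Rows are origins, columns destinations (order :data:`ROI_LABELS`);
    refixations of the same ROI are ignored (zero diagonal).
    """
    idx = {r: i for i, r in enumerate(ROI_LABELS)}
    m = np.zeros((len(ROI_LABELS), len(ROI_LABELS)), dtype=int)
    seq = [r for r in roi_sequence if r in idx]
    for a, b in zip(seq[:-1], seq[1:]):
        if a != b:
            m[idx[a], idx[b]] += 1
    return m


def relative_net_transitions(m: np.ndarray) -> float:
    """Relative net transitions R = sum|M - M^T| / sum(M + M^T) in [0, 1].

    R = 1 for purely one-directional transition flow, 0 for a fully
    symmetric matrix; NaN when the epoch has no transitions.
    """
    m = np.asarray(m, dtype=float)
    net = np.abs(m - m.T).sum()
    total = (m + m.T).sum()
    if total == 0:
        return float("nan")
    return float(net / total)


def transitions_table(fixations: pd.DataFrame) -> pd.DataFrame:
    """Per-trial mean relative net transitions per epoch kind.

    Fixation sequences are grouped per (trial, epoch kind, grasp index) =
    one epoch; epochs with fewer than two labeled fixations yield no
    value.  Returns subject, trial, trial_type, epoch_kind,
    relative_net_transitions (trial-level mean over its epochs).
    """
    fx = fixations[fixations.roi.notna() & fixations.epoch_kind.notna()]
    rows = []
    for (subj, trial, ttype, kind, k), grp in fx.groupby(
        ["subject", "trial", "trial_type", "epoch_kind", "grasp_index"]
    ):
        seq = grp.sort_values("onset").roi.tolist()
        if len(seq) < 2:
            continue
        r = relative_net_transitions(transition_matrix(seq))
        if r == r:
            rows.append({
                "subject": subj, "trial": trial, "trial_type": ttype,
                "epoch_kind": kind, "grasp_index": k, "R": r,
            })
    if not rows:
        return pd.DataFrame(columns=["subject", "trial", "trial_type", "epoch_kind", "relative_net_transitions"])
    per_epoch = pd.DataFrame(rows)
    return (
        per_epoch.groupby(["subject", "trial", "trial_type", "epoch_kind"])["R"]
        .mean()
        .rename("relative_net_transitions")
        .reset_index()
    )


# ---------------------------------------------------------------------------
# First-fixation latencies

def first_fixation_latencies(
    epochs: pd.DataFrame, fixations: pd.DataFrame
) -> pd.DataFrame:
    """Normalized latency of the first fixation on each ROI per epoch,
    aggregated to the per-trial median.

    Latency = (first fixation onset - epoch start) / epoch duration, in
    [0, 1]; a fixation is attributed to the epoch containing its onset.
    ROIs never fixated in any epoch of a trial are missing (no row), not
    zero.  Returns subject, trial, trial_type, epoch_kind, roi, latency.
    """
    fx = fixations[fixations.roi.notna() & fixations.epoch_kind.notna()]
    rows = []
    for ep in epochs.itertuples():
        sel = fx[
            (fx.subject == ep.subject) & (fx.trial == ep.trial)
            & (fx.epoch_kind == ep.epoch_kind) & (fx.grasp_index == ep.grasp_index)
        ]
        if sel.empty or ep.duration <= 0:
            continue
        firsts = sel.sort_values("onset").groupby("roi", sort=False)["onset"].first()
        for roi, onset in firsts.items():
            lat = (onset - ep.start) / ep.duration
            rows.append({
                "subject": ep.subject, "trial": ep.trial, "trial_type": ep.trial_type,
                "epoch_kind": ep.epoch_kind, "grasp_index": ep.grasp_index,
                "roi": roi, "latency": float(np.clip(lat, 0.0, 1.0)),
            })
    if not rows:
        return pd.DataFrame(columns=["subject", "trial", "trial_type", "epoch_kind", "roi", "latency"])
    per_epoch = pd.DataFrame(rows)
    return (
        per_epoch.groupby(["subject", "trial", "trial_type", "epoch_kind", "roi"])["latency"]
        .median()
        .reset_index()
    )
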