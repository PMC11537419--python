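"""Fixation/saccade event detection from raw gaze direction streams.

The pipeline mirrors standard practice for head-mounted eye trackers
sampling a cyclopean gaze direction at ~120 Hz:

1.  horizontal/vertical gaze angles from the unit direction vector,
    ``theta_h = (180/pi) * arctan(x/z)``, ``theta_v = (180/pi) * arctan(y/z)``;
2.  angular velocity as the first difference of the angles over time,
    ``omega = sqrt(omega_h**2 + omega_v**2)``, assigned to the later
    timestamp of each sample pair;
3.  an adaptive saccade velocity threshold: starting from 200 deg/s, the
    threshold is repeatedly re-estimated from the sub-threshold velocity
    samples as their median plus 3x their median absolute deviation (MAD,
    unscaled) until it changes by no more than 1 deg/s.  The dispersion
    term alone is not a fixed point of the iteration — for any velocity
    distribution with density vanishing at zero, pure k*MAD truncation
    contracts to zero — so the robust center is included, as in the
    adaptive-threshold saccade-detection literature;
4.  run-length classification of velocity samples into fixations (below
    threshold) and saccades (above), followed by two merge rules: saccades
    shorter than 30 ms bracketed by fixations are absorbed into a single
    fixation, then fixations shorter than 50 ms bracketed by saccades are
    relabeled saccade;
5.  fixation filtering: fixations shorter than 100 ms are dropped, and
    fixations longer than a robust upper fence (population median plus
    3.5x MAD of fixation durations) are rejected as outliers.

Samples with ``z == 0`` (gaze orthogonal to the forward axis) are flagged
invalid and excluded; recording gaps longer than twice the nominal sample
interval split events rather than being interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

DEG = 180.0 / np.pi


@dataclass
class SaccadeDetectionParams:
    """Tunable constants of the event detector (units in names/docs).

    All values are strictly positive; defaults follow common usage for
    120 Hz VR eye tracking.
    """

    theta0: float = 200.0           # initial velocity threshold, deg/s
    mad_multiplier: float = 3.0     # threshold = median + multiplier * MAD of sub-threshold omega
    convergence_tol: float = 1.0    # deg/s
    max_iterations: int = 100
    merge_saccade_max: float = 0.030   # s, rule (a)
    merge_fixation_max: float = 0.050  # s, rule (b)
    fixation_min: float = 0.100        # s
    fixation_mad_reject: float = 3.5   # upper fence = median + 3.5 * MAD
    gap_factor: float = 2.0            # gaps > factor * nominal dt split events

    def __post_init__(self) -> None:
        for name in (
            "theta0", "mad_multiplier", "convergence_tol", "merge_saccade_max",
            "merge_fixation_max", "fixation_min", "fixation_mad_reject", "gap_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class VelocityTrace:
    """Angular velocity series; entry i spans (t[i-1]_sample, t[i]_sample]."""

    t: np.ndarray        # timestamp of the later sample of each pair, s
    omega_h: np.ndarray  # deg/s
    omega_v: np.ndarray  # deg/s
    omega: np.ndarray    # deg/s, magnitude
    t_prev: np.ndarray   # timestamp of the earlier sample of each pair, s


@dataclass
class GazeEvent:
    """One fixation or saccade interval."""

    kind: str            # "fixation" | "saccade"
    onset: float         # s
    end: float           # s
    mean_dir: Optional[np.ndarray] = None  # unit vector, fixations only

    @property
    def duration(self) -> float:
        return self.end - self.onset


def compute_gaze_angles(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Horizontal/vertical gaze angles (degrees) from unit direction vectors.

    Returns ``(theta_h, theta_v, valid)``; samples with a zero forward
    component are flagged invalid (angles set to NaN) and must be excluded
    from velocity computation.
    """
    dirs = np.asarray(dirs, dtype=float)
    if dirs.ndim != 2 or dirs.shape[1] != 3:
        raise ValueError("dirs must be an (N, 3) array")
    x, y, z = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    valid = z != 0
    ratio_h = np.divide(x, z, out=np.zeros_like(x), where=valid)
    ratio_v = np.divide(y, z, out=np.zeros_like(y), where=valid)
    theta_h = np.where(valid, DEG * np.arctan(ratio_h), np.nan)
    theta_v = np.where(valid, DEG * np.arctan(ratio_v), np.nan)
    return theta_h, theta_v, valid


def compute_angular_velocity(
    t: np.ndarray, theta_h: np.ndarray, theta_v: np.ndarray
) -> VelocityTrace:
    """First-difference angular velocity, assigned to the later timestamp.

    Raises
    ------
    ValueError
        On fewer than two valid samples or non-increasing timestamps
        (the offending index is named).
    """
    t = np.asarray(t, dtype=float)
    theta_h = np.asarray(theta_h, dtype=float)
    theta_v = np.asarray(theta_v, dtype=float)
    valid = ~(np.isnan(theta_h) | np.isnan(theta_v))
    t, theta_h, theta_v = t[valid], theta_h[valid], theta_v[valid]
    if t.size < 2:
        raise ValueError("need at least two valid samples")
    dt = np.diff(t)
    bad = np.where(dt <= 0)[0]
    if bad.size:
        raise ValueError(f"non-increasing timestamp at sample index {int(bad[0]) + 1}")
    omega_h = np.diff(theta_h) / dt
    omega_v = np.diff(theta_v) / dt
    return VelocityTrace(
        t=t[1:],
        omega_h=omega_h,
        omega_v=omega_v,
        omega=np.hypot(omega_h, omega_v),
        t_prev=t[:-1],
    )


def _mad(x: np.ndarray) -> float:
    """Raw median absolute deviation (no normal-consistency scaling)."""
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def adaptive_saccade_threshold(
    trace: VelocityTrace, params: SaccadeDetectionParams = SaccadeDetectionParams()
) -> tuple[float, int]:
    """Iterated MAD-based saccade velocity threshold.

    ``theta_{n+1} = median + mad_multiplier * MAD`` of
    ``{omega : omega < theta_n}``, until the change is at most
    ``convergence_tol``.  Returns ``(threshold deg/s, n_iterations)``.

    Degenerate inputs: if no samples fall below the current threshold the
    current value is returned with a warning; an all-zero trace converges
    to 0 in one step.
    """
    omega = np.asarray(trace.omega, dtype=float)
    if omega.size == 0:
        raise ValueError("empty velocity trace")
    theta = params.theta0
    for iteration in range(1, params.max_iterations + 1):
        below = omega[omega < theta]
        if below.size == 0:
            warnings.warn(
                f"no velocity samples below threshold {theta:.1f} deg/s; returning it unchanged"
            )
            return theta, iteration
        new_theta = float(np.median(below)) + params.mad_multiplier * _mad(below)
        if new_theta == 0.0:
            # all sub-threshold velocities are zero: converged
            return 0.0, iteration
        if abs(new_theta - theta) <= params.convergence_tol:
            return new_theta, iteration
        theta = new_theta
    raise RuntimeError(
        f"adaptive threshold failed to converge in {params.max_iterations} iterations"
    )


def _runs(labels: np.ndarray) -> list[tuple[int, int, bool]]:
    """Contiguous runs of a boolean array as (start, stop_exclusive, value)."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i, bool(labels[start])))
            start = i
    return out


def classify_and_merge(
    trace: VelocityTrace,
    threshold: float,
    params: SaccadeDetectionParams = SaccadeDetectionParams(),
) -> list[GazeEvent]:
    """Classify velocity samples into fixation/saccade events and merge
    minuscule events.

    A velocity sample covers the interval between its two source samples;
    an event spans from the earlier timestamp of its first velocity sample
    to the later timestamp of its last.  Recording gaps longer than
    ``gap_factor`` nominal sample intervals split the stream into
    independently classified segments.

    Merge rules, applied in order, one pass each: (a) saccades shorter
    than ``merge_saccade_max`` bracketed by fixations are relabeled and
    the three events merged into one fixation; (b) fixations shorter than
    ``merge_fixation_max`` bracketed by saccades become part of a single
    saccade.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    omega = np.asarray(trace.omega, dtype=float)
    if omega.size == 0:
        return []
    dt = trace.t - trace.t_prev
    nominal_dt = float(np.median(dt))
    gap = dt > params.gap_factor * nominal_dt

    events: list[GazeEvent] = []
    is_fix = omega <= threshold
    # segment boundaries at gaps: a gap velocity sample is dropped entirely
    seg_start = 0
    boundaries = list(np.where(gap)[0]) + [omega.size]
    for b in boundaries:
        if b > seg_start:
            for s, e, fix in _runs(is_fix[seg_start:b]):
                s += seg_start
                e += seg_start
                events.append(
                    GazeEvent(
                        kind="fixation" if fix else "saccade",
                        onset=float(trace.t_prev[s]),
                        end=float(trace.t[e - 1]),
                    )
                )
        seg_start = b + 1

    events = merge_events(events, params)
    return events


def merge_events(
    events: list[GazeEvent], params: SaccadeDetectionParams = SaccadeDetectionParams()
) -> list[GazeEvent]:
    """Apply the two merge rules; idempotent on its own output.

    Events merge only when temporally adjacent (no recording gap between
    them).
    """

    def adjacent(a: GazeEvent, b: GazeEvent) -> bool:
        return np.isclose(a.end, b.onset)

    # rule (a): short saccade bracketed by fixations -> one fixation
    out: list[GazeEvent] = []
    i = 0
    while i < len(events):
        ev = events[i]
        if (
            ev.kind == "saccade"
            and ev.duration < params.merge_saccade_max
            and out
            and out[-1].kind == "fixation"
            and i + 1 < len(events)
            and events[i + 1].kind == "fixation"
            and adjacent(out[-1], ev)
            and adjacent(ev, events[i + 1])
        ):
            out[-1] = GazeEvent("fixation", out[-1].onset, events[i + 1].end)
            i += 2
        else:
            out.append(ev)
            i += 1
    events = out

    # rule (b): short fixation bracketed by saccades -> one saccade
    out = []
    i = 0
    while i < len(events):
        ev = events[i]
        if (
            ev.kind == "fixation"
            and ev.duration < params.merge_fixation_max
            and out
            and out[-1].kind == "saccade"
            and i + 1 < len(events)
            and events[i + 1].kind == "saccade"
            and adjacent(out[-1], ev)
            and adjacent(ev, events[i + 1])
        ):
            out[-1] = GazeEvent("saccade", out[-1].onset, events[i + 1].end)
            i += 2
        else:
            out.append(ev)
            i += 1
    return out


def filter_fixations(
    events: list[GazeEvent], params: SaccadeDetectionParams = SaccadeDetectionParams()
) -> tuple[list[GazeEvent], dict]:
    """Duration-based fixation rejection.

    Fixations shorter than ``fixation_min`` are removed; fixations longer
    than ``median + fixation_mad_reject * MAD`` of the remaining fixation
    durations are rejected as outliers.  When the duration MAD is zero
    (e.g. identical durations) the outlier step is skipped with a warning.

    Returns the retained fixations (saccades are not passed through) and a
    report dict with the rejection fraction of the outlier rule.
    """
    fixations = [e for e in events if e.kind == "fixation"]
    long_enough = [e for e in fixations if e.duration >= params.fixation_min]
    n_short = len(fixations) - len(long_enough)
    if not long_enough:
        warnings.warn("no fixations of at least minimum duration")
        return [], {"n_short": n_short, "n_outlier": 0, "rejection_fraction": 0.0}
    durations = np.array([e.duration for e in long_enough])
    mad = _mad(durations)
    if mad < 1e-9:  # effectively identical durations
        warnings.warn("fixation-duration MAD is zero; skipping outlier rejection")
        kept = long_enough
    else:
        fence = float(np.median(durations)) + params.fixation_mad_reject * mad
        kept = [e for e in long_enough if e.duration <= fence]
    n_outlier = len(long_enough) - len(kept)
    report = {
        "n_short": n_short,
        "n_outlier": n_outlier,
        "rejection_fraction": n_outlier / len(long_enough),
    }
    if not kept:
        warnings.warn("all fixations rejected")
    return kept, report


def detect_fixations(
    t: np.ndarray,
    dirs: np.ndarray,
    params: SaccadeDetectionParams = SaccadeDetectionParams(),
    apply_duration_filter: bool = True,
) -> tuple[list[GazeEvent], dict]:
    """Full detection pipeline: angles -> velocity -> adaptive threshold ->
    classification/merging -> optional duration filtering.

    Fixation events carry the mean gaze direction of their samples.
    Returns ``(fixations, report)``; the report records the converged
    threshold, iteration count and rejection statistics.
    """
    t = np.asarray(t, dtype=float)
    dirs = np.asarray(dirs, dtype=float)
    theta_h, theta_v, valid = compute_gaze_angles(dirs)
    trace = compute_angular_velocity(t, theta_h, theta_v)
    threshold, n_iter = adaptive_saccade_threshold(trace, params)
    events = classify_and_merge(trace, threshold, params)
    report: dict = {"threshold": threshold, "iterations": n_iter,
                    "n_events": len(events)}
    if apply_duration_filter:
        fixations, filt = filter_fixations(events, params)
        report.update(filt)
    else:
        fixations = [e for e in events if e.kind == "fixation"]
    # mean direction per fixation
    tv = t[valid]
    dv = dirs[valid]
    for ev in fixations:
        sel = (tv >= ev.onset) & (tv <= ev.end)
        if sel.any():
            m = dv[sel].mean(axis=0)
            n = np.linalg.norm(m)
            ev.mean_dir = m / n if n > 0 else None
    return fixations, report
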