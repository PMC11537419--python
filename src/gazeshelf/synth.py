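"""Synthetic experimental sessions: trials, agent moves, gaze and
controller streams with full ground truth.

The generator emulates the statistical structure of a VR shelf-sorting
experiment: a simulated subject performs 24 trials (each of the 12 sorting
instructions twice, shuffled), displacing objects on a 5x5 shelf.  For
every object displacement the timeline contains a *preparation* epoch
(previous grasp end to current grasp onset) and an *execution* epoch
(grasp onset to grasp end).  Gaze is emitted as a 120 Hz stream of unit
direction vectors following an action-locked fixation schedule:

* early preparation: fixations on the previous action's drop-off location
  and on task-irrelevant objects/shelves (visual search);
* after a configurable fraction of the preparation epoch has elapsed
  (default 0.42 EASY / 0.46 HARD), fixations lock onto the current target
  object until grasp onset — the just-in-time pattern;
* first half of execution: fixations stay on the grasped object's pickup
  location; then the gaze moves to the drop-off shelf, and late in the
  epoch to the next action's target and other regions.

Fixation durations are truncated-lognormal (median 350 ms, floor 100 ms);
consecutive fixations on the same shelf cell are separated by small
intra-cell displacements large enough to produce detectable saccades at
120 Hz.  Saccades are constant-velocity great-circle sweeps.  Controller
position moves linearly between cells with the trigger held during
execution epochs.  Everything emitted is logged as ground truth (moves,
grasps, epochs, fixations with action-relative ROI labels), so the
analysis pipeline can be validated by round-trip comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .epochs import Epoch, GraspEvent, label_fixation, segment_epochs, state_before_grasp
from .instructions import (
    INSTRUCTIONS,
    Instruction,
    goal_grid,
    instruction_lines,
    object_code,
    score_grid,
)
from .shelf import Cell, Move, ShelfGeometry, ShelfState, generate_initial_configuration
from .solver import greedy_solve, legal_moves


@dataclass
class AgentPolicy:
    """How the simulated agent chooses among strictly score-improving moves.

    ``greedy_optimal`` replays the steepest-ascent model trajectory;
    ``spatial_heuristic`` prefers pickups near the top-left and avoids
    dropping objects into the bottom row / rightmost column, emulating the
    human spatial strategy; ``random_valid`` picks uniformly among the
    improving moves.
    """

    kind: str = "greedy_optimal"
    pickup_bias: float = 1.0   # spatial_heuristic: weight on (row+col) of the pickup
    drop_avoid: float = 1.0    # spatial_heuristic: penalty for bottom-row/right-column drops


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic experiment.

    Epoch-duration and fixation-schedule defaults are the observed means
    of the emulated experiment; the fixation-duration shape (0.17) puts
    ~2.4% of fixation durations above the median + 3.5 MAD outlier fence.
    """

    sample_rate: float = 120.0            # Hz
    prep_mean: dict = field(default_factory=lambda: {"EASY": 2.10, "HARD": 4.05})   # s
    exec_mean: dict = field(default_factory=lambda: {"EASY": 1.76, "HARD": 2.15})   # s
    epoch_sigma: float = 0.25             # lognormal shape of epoch durations
    epoch_min: float = 0.8                # s
    first_target_fraction: dict = field(default_factory=lambda: {"EASY": 0.42, "HARD": 0.46})
    fixation_median: float = 0.350        # s
    fixation_sigma: float = 0.17          # lognormal shape
    fixation_min: float = 0.100           # s
    saccade_velocity: float = 400.0       # deg/s
    saccade_min: float = 0.032            # s; above the 30 ms merge rule
    saccade_max: float = 0.060            # s
    noise_sd_deg: float = 0.5             # isotropic angular noise on directions
    noise_ar: float = 0.9                 # AR(1) coefficient of the angular noise
                                          # (trackers low-pass their output; white
                                          # noise at 120 Hz would imply implausible
                                          # ~100 deg/s fixational velocities)
    hand_noise_sd: float = 0.0            # m, controller position noise
    intertrial_gap: float = 1.0           # s
    trial_tail: float = 0.5               # s of idle gaze after the last grasp
    move_cap: int = 60
    geometry: ShelfGeometry = field(default_factory=ShelfGeometry)

    def __post_init__(self) -> None:
        for d in (self.prep_mean, self.exec_mean):
            if any(v <= 0 for v in d.values()):
                raise ValueError("epoch duration means must be positive")
        if any(not 0 <= v <= 1 for v in self.first_target_fraction.values()):
            raise ValueError("first_target_fraction must lie in [0, 1]")
        if self.fixation_min <= 0 or self.fixation_median <= 0:
            raise ValueError("fixation durations must be positive")


@dataclass
class TrialRecording:
    """One simulated trial: raw streams plus complete ground truth."""

    subject: int
    trial: int
    instruction: Instruction
    initial_state: ShelfState
    trial_start: float
    trial_end: float
    t_gaze: np.ndarray          # s
    gaze_dir: np.ndarray        # (N, 3) unit vectors
    t_ctrl: np.ndarray          # s
    trigger: np.ndarray         # bool
    ctrl_pos: np.ndarray        # (N, 3) m
    truth_moves: list[Move]
    truth_grasps: list[GraspEvent]
    truth_epochs: list[Epoch]
    truth_fixations: pd.DataFrame   # onset, end, duration, row, col, occupied, roi, grasp_index, epoch_kind
    solved: bool

    @property
    def trial_type(self) -> str:
        return self.instruction.trial_type


@dataclass
class SessionRecording:
    """All trials of one simulated subject."""

    subject: int
    trials: list[TrialRecording]

    def gaze_stream(self) -> tuple[np.ndarray, np.ndarray]:
        t = np.concatenate([tr.t_gaze for tr in self.trials])
        d = np.concatenate([tr.gaze_dir for tr in self.trials])
        return t, d


# ---------------------------------------------------------------------------
# Agent move simulation

def _improving_moves(grid, lines, instruction, visited, n_rows, n_cols):
    cur = score_grid(grid, lines, instruction)
    out = []
    for src, dst in legal_moves(grid, n_rows, n_cols):
        code = grid.pop(src)
        grid[dst] = code
        s = score_grid(grid, lines, instruction)
        key = frozenset(grid.items())
        del grid[dst]
        grid[src] = code
        if s > cur and key not in visited:
            out.append((src, dst, s))
    return out


def simulate_agent_moves(
    state: ShelfState,
    instruction: Instruction,
    policy: AgentPolicy,
    rng: np.random.Generator,
    move_cap: int = 60,
) -> tuple[list[Move], bool]:
    """Generate the agent's move sequence for one trial.

    Every emitted move is legal; the sequence ends at the instruction's
    goal, at a local score maximum, or at ``move_cap`` (in the latter two
    cases ``solved`` is False and the partial sequence is returned).
    """
    if policy.kind == "greedy_optimal":
        res = greedy_solve(state, instruction, move_cap=move_cap, method="steepest")
        return res.move_sequence, res.solved

    n_rows, n_cols = state.n_rows, state.n_cols
    lines = instruction_lines(instruction, n_rows, n_cols)
    grid = {cell: object_code(o.color, o.shape) for cell, o in state.cells() if o}
    visited = {frozenset(grid.items())}
    moves: list[Move] = []
    while not goal_grid(grid, lines, instruction) and len(moves) < move_cap:
        cands = _improving_moves(grid, lines, instruction, visited, n_rows, n_cols)
        if not cands:
            break
        if policy.kind == "random_valid":
            src, dst, _ = cands[int(rng.integers(len(cands)))]
        elif policy.kind == "spatial_heuristic":
            # prefer pickups from the top-left, avoid drops into the
            # bottom row / rightmost column; small jitter breaks ties
            def cost(cand):
                (pr, pc), (dr, dc), s = cand
                forbidden = float(dr == n_rows or dc == n_cols)
                return (
                    policy.pickup_bias * (pr + pc)
                    + policy.drop_avoid * 4.0 * forbidden
                    - 0.1 * s
                    + rng.uniform(0, 0.5)
                )
            src, dst, _ = min(cands, key=cost)
        else:
            raise ValueError(f"unknown policy kind {policy.kind!r}")
        grid[dst] = grid.pop(src)
        visited.add(frozenset(grid.items()))
        moves.append(Move(src, dst))
    return moves, goal_grid(grid, lines, instruction)


# ---------------------------------------------------------------------------
# Gaze synthesis helpers

def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.degrees(np.arccos(np.clip(a @ b, -1.0, 1.0))))


def _slerp(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Great-circle interpolation between unit vectors for fractions f."""
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if omega < 1e-9:
        return np.tile(a, (len(f), 1))
    so = np.sin(omega)
    return (
        np.sin((1 - f)[:, None] * omega) * a[None, :] + np.sin(f[:, None] * omega) * b[None, :]
    ) / so


class _GazeTargeter:
    """Pick fixation points: cell centers plus intra-cell jitter.

    Consecutive points within the same cell are kept at least
    ``min_jump`` meters apart so the intervening saccade is detectable at
    the stream's sample rate, while staying within half a cell pitch of
    the center so the fixation still resolves to that cell.
    """

    def __init__(self, geometry: ShelfGeometry, rng: np.random.Generator):
        self.geom = geometry
        self.rng = rng
        self.max_off = 0.30 * (geometry.width / geometry.n_cols)   # m
        self.min_jump = 0.20                                        # m, between any two points
        self._last_plane: Optional[np.ndarray] = None

    def point(self, cell: Cell) -> np.ndarray:
        center = self.geom.cell_center(cell)
        for _ in range(30):
            off = self.rng.uniform(-self.max_off, self.max_off, size=2)
            plane = center[:2] + off
            if self._last_plane is None or np.linalg.norm(plane - self._last_plane) >= self.min_jump:
                break
        self._last_plane = plane
        p = np.array([plane[0], plane[1], center[2]])
        return p / np.linalg.norm(p)


def _draw_fix_duration(cfg: GeneratorConfig, rng: np.random.Generator) -> float:
    while True:
        d = cfg.fixation_median * np.exp(cfg.fixation_sigma * rng.standard_normal())
        if d >= cfg.fixation_min:
            return float(d)


def _draw_epoch_duration(mean: float, cfg: GeneratorConfig, rng: np.random.Generator) -> float:
    mu = np.log(mean) - cfg.epoch_sigma**2 / 2
    while True:
        d = float(np.exp(mu + cfg.epoch_sigma * rng.standard_normal()))
        if d >= cfg.epoch_min:
            return d


# ---------------------------------------------------------------------------
# Trial synthesis

def _roi_cell_chooser(
    segment: str,
    k: int,
    grasps_cells: list[tuple[Cell, Cell]],
    state_grid: set,
    all_cells: list[Cell],
    rng: np.random.Generator,
):
    """Return a function drawing target cells for one schedule segment.

    ``state_grid`` is the set of occupied cells before move k;
    ``grasps_cells[k]`` is (pickup, dropoff) of move k.
    """
    cur_pick, cur_drop = grasps_cells[k]
    nxt = grasps_cells[k + 1] if k + 1 < len(grasps_cells) else None
    prev = grasps_cells[k - 1] if k > 0 else None
    special = {cur_pick, cur_drop}
    if nxt:
        special |= {nxt[0], nxt[1]}
    if prev:
        special.add(prev[1])
    other_occ = [c for c in all_cells if c in state_grid and c not in special]
    other_emp = [c for c in all_cells if c not in state_grid and c not in special]

    def pick(options: list[tuple[float, object]]) -> Cell:
        opts = [(w, c) for w, c in options if c is not None]
        w = np.array([o[0] for o in opts])
        cells = [o[1] for o in opts]
        choice = cells[rng.choice(len(cells), p=w / w.sum())]
        if isinstance(choice, list):
            return choice[int(rng.integers(len(choice)))]
        return choice

    if segment == "prep_early":
        return lambda: pick([
            (0.30, prev[1] if prev else None),
            (0.35, other_occ or None),
            (0.20, other_emp or None),
            (0.06, nxt[0] if nxt else None),
            (0.04, nxt[1] if nxt else None),
            (0.05, cur_drop),
        ])
    if segment == "prep_target":
        return lambda: cur_pick
    if segment == "exec_object":
        return lambda: cur_pick
    if segment == "exec_shelf":
        return lambda: cur_drop
    if segment == "exec_late":
        return lambda: pick([
            (0.35, nxt[0] if nxt else None),
            (0.15, nxt[1] if nxt else None),
            (0.3, other_occ or None),
            (0.2, other_emp or None),
        ])
    raise ValueError(segment)


def _fill_segments(
    segments: list[tuple[float, object]],
    start: float,
    targeter: _GazeTargeter,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Fill the timeline with alternating fixations and saccades.

    ``segments`` is a list of (end_time, cell_chooser).  Returns event
    dicts with keys kind/onset/end/point/cell; events tile
    [start, segments[-1][0]] without gaps.  The first fixation of each
    segment is preceded by the saccade that brings gaze onto the
    segment's first target.
    """
    events: list[dict] = []
    t = start
    point = None
    eps = 1e-9
    for seg_end, chooser in segments:
        first_of_segment = True
        while t < seg_end - eps:
            cell = chooser()
            new_point = targeter.point(cell)
            if point is not None:
                amp = _angle_deg(point, new_point)
                sdur = float(np.clip(amp / cfg.saccade_velocity, cfg.saccade_min, cfg.saccade_max))
                # not enough room for a saccade plus a minimal fixation:
                # extend the current fixation to the segment end instead
                if t + sdur + cfg.fixation_min > seg_end and not first_of_segment and events:
                    events[-1]["end"] = seg_end
                    t = seg_end
                    break
                if t + sdur + cfg.fixation_min > seg_end and first_of_segment and events:
                    # segment too short to visit its target at all
                    events[-1]["end"] = seg_end
                    t = seg_end
                    break
                events.append({"kind": "saccade", "onset": t, "end": t + sdur,
                               "p0": point, "p1": new_point})
                t += sdur
            dur = _draw_fix_duration(cfg, rng)
            end = min(t + dur, seg_end)
            events.append({"kind": "fixation", "onset": t, "end": end,
                           "point": new_point, "cell": cell})
            t = end
            point = new_point
            first_of_segment = False
    return events


def _sample_gaze(
    events: list[dict], t0: float, t1: float, cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the event timeline into a direction stream at the configured
    rate, adding isotropic angular noise."""
    n = int(np.floor((t1 - t0) * cfg.sample_rate))
    ts = t0 + np.arange(n) / cfg.sample_rate
    dirs = np.empty((n, 3))
    onsets = np.array([e["onset"] for e in events])
    idx = np.searchsorted(onsets, ts, side="right") - 1
    idx = np.clip(idx, 0, len(events) - 1)
    for ei in np.unique(idx):
        sel = idx == ei
        ev = events[ei]
        if ev["kind"] == "fixation":
            dirs[sel] = ev["point"]
        else:
            dur = ev["end"] - ev["onset"]
            f = np.clip((ts[sel] - ev["onset"]) / max(dur, 1e-9), 0.0, 1.0)
            dirs[sel] = _slerp(ev["p0"], ev["p1"], f)
    if cfg.noise_sd_deg > 0 and n:
        sd = np.radians(cfg.noise_sd_deg)
        rho = cfg.noise_ar
        # stationary AR(1) noise per channel, marginal SD = noise_sd_deg
        g = rng.standard_normal((n, 2))
        ar = np.empty_like(g)
        ar[0] = g[0]
        innov = np.sqrt(1 - rho**2)
        for i in range(1, n):
            ar[i] = rho * ar[i - 1] + innov * g[i]
        ar *= sd
        # small-angle noise in the tangent plane of each direction
        ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(dirs, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(dirs, e1)
        dirs = dirs + ar[:, :1] * e1 + ar[:, 1:] * e2
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return ts, dirs


def _controller_stream(
    grasps: list[GraspEvent],
    geometry: ShelfGeometry,
    t0: float,
    t1: float,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trigger booleans and controller positions: linear travel between
    cells, trigger held exactly during execution epochs."""
    n = int(np.floor((t1 - t0) * cfg.sample_rate))
    ts = t0 + np.arange(n) / cfg.sample_rate
    rest = np.array([0.0, -0.6, 0.6])
    pos = np.tile(rest, (n, 1))
    trig = np.zeros(n, dtype=bool)
    waypoints = [(t0, rest)]
    for g in grasps:
        waypoints.append((g.onset, geometry.cell_center(g.pickup_cell)))
        waypoints.append((g.end, geometry.cell_center(g.dropoff_cell)))
    waypoints.append((t1, rest))
    for (ta, pa), (tb, pb) in zip(waypoints[:-1], waypoints[1:]):
        sel = (ts >= ta) & (ts < tb)
        if not sel.any() or tb <= ta:
            continue
        f = (ts[sel] - ta) / (tb - ta)
        pos[sel] = pa[None, :] + f[:, None] * (pb - pa)[None, :]
    for g in grasps:
        trig |= (ts >= g.onset) & (ts < g.end)
    if cfg.hand_noise_sd > 0:
        pos = pos + rng.standard_normal(pos.shape) * cfg.hand_noise_sd
    return ts, trig, pos


def simulate_trial(
    subject: int,
    trial: int,
    instruction: Instruction,
    config: GeneratorConfig,
    policy: AgentPolicy,
    rng: np.random.Generator,
    trial_start: float = 0.0,
) -> TrialRecording:
    """Simulate one complete trial (agent moves, epochs, gaze + controller
    streams, ground truth)."""
    geometry = config.geometry
    state = generate_initial_configuration(rng, n_rows=geometry.n_rows, n_cols=geometry.n_cols)
    moves, solved = simulate_agent_moves(state, instruction, policy, rng, config.move_cap)
    ttype = instruction.trial_type
    frac = config.first_target_fraction[ttype]

    # grasp timing
    grasps: list[GraspEvent] = []
    t = trial_start
    for k, mv in enumerate(moves):
        prep = _draw_epoch_duration(config.prep_mean[ttype], config, rng)
        exe = _draw_epoch_duration(config.exec_mean[ttype], config, rng)
        onset = t + prep
        grasps.append(GraspEvent(onset, onset + exe, mv.from_cell, mv.to_cell, k))
        t = onset + exe
    trial_end = t + config.trial_tail

    # gaze schedule
    grasp_cells = [(g.pickup_cell, g.dropoff_cell) for g in grasps]
    all_cells = geometry.all_cells()
    targeter = _GazeTargeter(geometry, rng)
    segments: list[tuple[float, object, int, str]] = []
    cur_state = state
    occ_by_move = []
    for k, g in enumerate(grasps):
        occ = set(cell for cell, obj in cur_state.cells() if obj)
        occ_by_move.append(occ)
        prep_start = grasps[k - 1].end if k > 0 else trial_start
        lock = prep_start + frac * (g.onset - prep_start)
        mid = g.onset + 0.5 * (g.end - g.onset)
        late = g.onset + 0.8 * (g.end - g.onset)
        segments.append((lock, _roi_cell_chooser("prep_early", k, grasp_cells, occ, all_cells, rng), k, "preparation"))
        segments.append((g.onset, _roi_cell_chooser("prep_target", k, grasp_cells, occ, all_cells, rng), k, "preparation"))
        segments.append((mid, _roi_cell_chooser("exec_object", k, grasp_cells, occ, all_cells, rng), k, "execution"))
        segments.append((late, _roi_cell_chooser("exec_shelf", k, grasp_cells, occ, all_cells, rng), k, "execution"))
        segments.append((g.end, _roi_cell_chooser("exec_late", k, grasp_cells, occ, all_cells, rng), k, "execution"))
        cur_state = cur_state.apply(moves[k])
    # idle lead-in/tail: look at arbitrary occupied cells
    def make_idle_chooser(occupied: set):
        cells = sorted(occupied) or all_cells[:1]

        def chooser():
            return cells[int(rng.integers(len(cells)))]

        return chooser

    idle_chooser = make_idle_chooser({cell for cell, obj in cur_state.cells() if obj})

    timeline: list[tuple[float, object]] = [(end, ch) for end, ch, _, _ in segments]
    timeline.append((trial_end, idle_chooser))
    events = _fill_segments(timeline, trial_start, targeter, config, rng)

    # ground-truth fixation table with action-relative ROI labels
    seg_bounds = [(end, k, kind) for end, _, k, kind in segments]
    rows = []
    for ev in events:
        if ev["kind"] != "fixation":
            continue
        ref = None
        kind = None
        for end, k, seg_kind in seg_bounds:
            if ev["onset"] < end - 1e-9:
                ref, kind = k, seg_kind
                break
        if ref is None:
            continue  # lead-in / tail fixations are outside any epoch
        occupied = ev["cell"] in occ_by_move[ref]
        roi = label_fixation(ev["cell"], occupied, grasps, ref)
        rows.append({
            "onset": ev["onset"], "end": ev["end"], "duration": ev["end"] - ev["onset"],
            "row": ev["cell"][0], "col": ev["cell"][1], "occupied": occupied,
            "roi": roi, "grasp_index": ref, "epoch_kind": kind,
        })
    truth_fix = pd.DataFrame(rows)

    t_gaze, gaze_dir = _sample_gaze(events, trial_start, trial_end, config, rng)
    t_ctrl, trigger, ctrl_pos = _controller_stream(grasps, geometry, trial_start, trial_end, config, rng)
    epochs = segment_epochs(grasps, trial_start) if grasps else []

    return TrialRecording(
        subject=subject, trial=trial, instruction=instruction,
        initial_state=state, trial_start=trial_start, trial_end=trial_end,
        t_gaze=t_gaze, gaze_dir=gaze_dir,
        t_ctrl=t_ctrl, trigger=trigger, ctrl_pos=ctrl_pos,
        truth_moves=moves, truth_grasps=grasps, truth_epochs=epochs,
        truth_fixations=truth_fix, solved=solved,
    )


def session_instructions(rng: np.random.Generator) -> list[Instruction]:
    """24-trial instruction sequence: each of the 12 subtypes twice, shuffled."""
    ids = list(INSTRUCTIONS) * 2
    order = rng.permutation(len(ids))
    return [INSTRUCTIONS[ids[i]] for i in order]


def simulate_session(
    config: GeneratorConfig,
    n_subjects: int = 1,
    policy: AgentPolicy = AgentPolicy(),
    seed: int | np.random.Generator = 0,
) -> list[SessionRecording]:
    """Simulate complete sessions for ``n_subjects`` subjects.

    Each subject receives an independent substream of the seed, so
    sessions are reproducible individually and jointly.
    """
    root = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n_subjects)
    sessions = []
    for s, sub_seed in enumerate(seeds):
        rng = np.random.default_rng(sub_seed)
        instructions = session_instructions(rng)
        t0 = 0.0
        trials = []
        for i, ins in enumerate(instructions):
            tr = simulate_trial(s, i, ins, config, policy, rng, trial_start=t0)
            trials.append(tr)
            t0 = tr.trial_end + config.intertrial_gap
        sessions.append(SessionRecording(subject=s, trials=trials))
    return sessions
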