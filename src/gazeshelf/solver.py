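"""Greedy task model for the shelf-sorting instructions, plus a BFS oracle.

The model estimates how many object displacements a purely score-driven
agent needs to satisfy a sorting instruction from a given initial
configuration.  Two search procedures are provided:

``method="steepest"``
    Steepest-ascent hill climbing: at every step scan all legal
    displacements (occupied cell -> empty cell), take the best strictly
    score-improving successor not visited before, stop at the goal or at a
    local score maximum.  ``n_moves`` is the trajectory length; this is the
    variant the synthetic agent replays, because its move sequence is the
    path actually walked.

``method="stack"``
    A literal stack-based search: while scanning a state's successors in a
    fixed order, every successor that beats the best score seen so far in
    the scan is pushed onto the stack (duplicates blocked by a visited
    set); the search then continues from the top of the stack, backtracking
    to earlier pushed states when a branch dead-ends, and stops as soon as
    a popped state satisfies the instruction.  ``n_moves`` here is the
    total number of states ever pushed (the length of the push history,
    initial configuration included), which exceeds the trajectory length
    whenever the scan records several successively better successors or
    the search backtracks.  This count is the model's "number of moves"
    quoted when comparing with human displacement counts.

The constrained variant excludes destination cells in the bottom row or the
rightmost column, emulating the spatial drop-off heuristic humans exhibit;
under it the stack search can exhaust all score-improving continuations
without reaching the goal (``solved=False``).

A breadth-first-search oracle gives exact minimal move counts on reduced
instances for validation.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .instructions import (
    Instruction,
    goal_grid,
    instruction_lines,
    object_code,
    score_grid,
)
from .shelf import Cell, Move, ShelfState


@dataclass
class SolverResult:
    """Outcome of one greedy search."""

    n_moves: int
    solved: bool
    move_sequence: list[Move]
    final_score: int
    states_explored: int
    cap_hit: bool = False
    method: str = "steepest"

    def to_dict(self) -> dict:
        return {
            "n_moves": self.n_moves,
            "solved": self.solved,
            "final_score": self.final_score,
            "states_explored": self.states_explored,
            "cap_hit": self.cap_hit,
            "method": self.method,
            "move_sequence": [
                {"from": list(m.from_cell), "to": list(m.to_cell)} for m in self.move_sequence
            ],
        }


def _grid_of(state: ShelfState) -> dict[Cell, int]:
    return {cell: object_code(obj.color, obj.shape) for cell, obj in state.cells() if obj}


def _grid_key(grid: dict[Cell, int]) -> frozenset:
    return frozenset(grid.items())


def legal_moves(
    grid: dict[Cell, int],
    n_rows: int,
    n_cols: int,
    constrained: bool = False,
) -> list[tuple[Cell, Cell]]:
    """All (from, to) displacement pairs in deterministic scan order.

    Sources and destinations are scanned row-major (top row first, left to
    right).  When ``constrained``, destinations in the bottom row or the
    rightmost column are excluded.
    """
    occupied = sorted(grid)
    empties = [
        (r, c)
        for r in range(1, n_rows + 1)
        for c in range(1, n_cols + 1)
        if (r, c) not in grid
    ]
    if constrained:
        empties = [(r, c) for (r, c) in empties if r != n_rows and c != n_cols]
    return [(src, dst) for src in occupied for dst in empties]


def _solve_steepest(
    grid: dict[Cell, int],
    instruction: Instruction,
    n_rows: int,
    n_cols: int,
    constrained: bool,
    move_cap: int,
    rng: Optional[np.random.Generator],
) -> SolverResult:
    lines = instruction_lines(instruction, n_rows, n_cols)
    visited = {_grid_key(grid)}
    moves: list[Move] = []
    score = score_grid(grid, lines, instruction)
    explored = 0
    cap_hit = False

    while not goal_grid(grid, lines, instruction):
        if len(moves) >= move_cap:
            cap_hit = True
            break
        best_score = score
        best: list[tuple[Cell, Cell]] = []
        for src, dst in legal_moves(grid, n_rows, n_cols, constrained):
            code = grid.pop(src)
            grid[dst] = code
            s = score_grid(grid, lines, instruction)
            key = _grid_key(grid)
            del grid[dst]
            grid[src] = code
            explored += 1
            if s <= score or key in visited:
                continue
            if s > best_score:
                best_score = s
                best = [(src, dst)]
            elif s == best_score:
                best.append((src, dst))
        if not best:
            break
        if rng is not None and len(best) > 1:
            src, dst = best[int(rng.integers(len(best)))]
        else:
            src, dst = best[0]
        grid[dst] = grid.pop(src)
        visited.add(_grid_key(grid))
        moves.append(Move(src, dst))
        score = best_score

    return SolverResult(
        n_moves=len(moves),
        solved=goal_grid(grid, lines, instruction),
        move_sequence=moves,
        final_score=score,
        states_explored=explored,
        cap_hit=cap_hit,
        method="steepest",
    )


def _solve_stack(
    grid: dict[Cell, int],
    instruction: Instruction,
    n_rows: int,
    n_cols: int,
    constrained: bool,
    pop_cap: int,
) -> SolverResult:
    lines = instruction_lines(instruction, n_rows, n_cols)
    # stack entries: (grid, move path from the initial state)
    stack: list[tuple[dict[Cell, int], tuple[Move, ...]]] = [(grid, ())]
    visited = {_grid_key(grid)}
    n_pushed = 1  # the initial configuration counts as pushed
    pops = 0
    cap_hit = False

    while stack:
        g, path = stack.pop()
        pops += 1
        if goal_grid(g, lines, instruction):
            return SolverResult(
                n_moves=n_pushed,
                solved=True,
                move_sequence=list(path),
                final_score=score_grid(g, lines, instruction),
                states_explored=pops,
                method="stack",
            )
        if pops > pop_cap:
            cap_hit = True
            break
        best = score_grid(g, lines, instruction)
        for src, dst in legal_moves(g, n_rows, n_cols, constrained):
            code = g.pop(src)
            g[dst] = code
            s = score_grid(g, lines, instruction)
            key = _grid_key(g)
            if s > best and key not in visited:
                visited.add(key)
                stack.append((dict(g), path + (Move(src, dst),)))
                n_pushed += 1
                best = s
            del g[dst]
            g[src] = code

    return SolverResult(
        n_moves=n_pushed,
        solved=False,
        move_sequence=[],
        final_score=0,
        states_explored=pops,
        cap_hit=cap_hit,
        method="stack",
    )


def greedy_solve(
    state: ShelfState,
    instruction: Instruction,
    constrained: bool = False,
    move_cap: int = 200,
    pop_cap: int = 20_000,
    method: str = "steepest",
    rng: Optional[np.random.Generator] = None,
) -> SolverResult:
    """Run the greedy task model from ``state`` under ``instruction``.

    Parameters
    ----------
    constrained
        Forbid destinations in the bottom row / rightmost column.
    move_cap
        Trajectory cap for the steepest variant.
    pop_cap
        Explored-state cap for the stack variant.
    method
        ``"steepest"`` or ``"stack"`` (see module docstring).
    rng
        Optional generator for random tie-breaking (steepest variant only);
        by default ties are broken by scan order.
    """
    grid = _grid_of(state)
    if method == "steepest":
        return _solve_steepest(
            grid, instruction, state.n_rows, state.n_cols, constrained, move_cap, rng
        )
    if method == "stack":
        return _solve_stack(grid, instruction, state.n_rows, state.n_cols, constrained, pop_cap)
    raise ValueError(f"unknown method {method!r}")


def bfs_oracle(
    state: ShelfState,
    instruction: Instruction,
    depth_cap: int = 12,
    node_budget: int = 2_000_000,
) -> Optional[int]:
    """Exact minimal number of moves to any goal state, by breadth-first
    search over the move graph.  Intended for reduced instances (small
    shelves / few objects); returns ``None`` when no goal state is
    reachable within ``depth_cap``.

    Raises
    ------
    RuntimeError
        If the search visits more than ``node_budget`` states.
    """
    n_rows, n_cols = state.n_rows, state.n_cols
    lines = instruction_lines(instruction, n_rows, n_cols)
    grid = _grid_of(state)
    if goal_grid(grid, lines, instruction):
        return 0

    seen = {_grid_key(grid)}
    frontier = deque([(grid, 0)])
    while frontier:
        cur, depth = frontier.popleft()
        if depth >= depth_cap:
            continue
        for src, dst in legal_moves(cur, n_rows, n_cols):
            nxt = dict(cur)
            nxt[dst] = nxt.pop(src)
            key = _grid_key(nxt)
            if key in seen:
                continue
            if goal_grid(nxt, lines, instruction):
                return depth + 1
            seen.add(key)
            if len(seen) > node_budget:
                raise RuntimeError("bfs_oracle node budget exceeded")
            frontier.append((nxt, depth + 1))
    return None
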