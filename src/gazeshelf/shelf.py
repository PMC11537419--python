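"""Shelf domain types: objects, the 5x5 grid, moves, and viewing geometry.

The task world is a wall-mounted shelf of ``n_rows`` x ``n_cols`` cubbies
holding distinctly featured objects (four colors x four shapes = 16 objects
on the default 5x5 shelf).  Rows are numbered 1..n_rows top to bottom and
columns 1..n_cols left to right; a cell is a ``(row, col)`` pair in that
1-based convention throughout the package.

World coordinates follow the VR convention used for the gaze streams:
x to the right, y up, z forward (from the observer toward the shelf).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

COLORS = ("red", "blue", "green", "yellow")
SHAPES = ("cube", "sphere", "pyramid", "cylinder")

Cell = tuple[int, int]


@dataclass(frozen=True, order=True)
class ObjectSpec:
    """One shelf object, identified by its (color, shape) feature pair."""

    color: str
    shape: str

    def __post_init__(self) -> None:
        if self.color not in COLORS:
            raise ValueError(f"unknown color {self.color!r}")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")


def all_objects() -> list[ObjectSpec]:
    """The full 16-object inventory: each (color, shape) pair exactly once."""
    return [ObjectSpec(c, s) for c in COLORS for s in SHAPES]


@dataclass(frozen=True)
class Move:
    """One object displacement: pick up at ``from_cell``, drop at ``to_cell``."""

    from_cell: Cell
    to_cell: Cell

    def __post_init__(self) -> None:
        if self.from_cell == self.to_cell:
            raise ValueError("move must change the cell")


class ShelfState:
    """Immutable snapshot of the shelf grid.

    Cells hold an :class:`ObjectSpec` or ``None``.  States are hashable and
    comparable so search code can keep visited sets.
    """

    __slots__ = ("_grid", "n_rows", "n_cols", "_key")

    def __init__(self, grid: dict[Cell, ObjectSpec], n_rows: int = 5, n_cols: int = 5):
        for (r, c), obj in grid.items():
            if not (1 <= r <= n_rows and 1 <= c <= n_cols):
                raise ValueError(f"cell ({r},{c}) outside {n_rows}x{n_cols} shelf")
            if obj is None:
                raise ValueError("grid dict must not contain None values")
        self.n_rows = n_rows
        self.n_cols = n_cols
        self._grid = dict(grid)
        self._key = tuple(sorted((cell, obj) for cell, obj in self._grid.items()))

    # -- basic access ------------------------------------------------------
    def __getitem__(self, cell: Cell) -> Optional[ObjectSpec]:
        return self._grid.get(cell)

    def occupied_cells(self) -> list[Cell]:
        return sorted(self._grid)

    def empty_cells(self) -> list[Cell]:
        return [
            (r, c)
            for r in range(1, self.n_rows + 1)
            for c in range(1, self.n_cols + 1)
            if (r, c) not in self._grid
        ]

    def objects(self) -> list[ObjectSpec]:
        return [self._grid[c] for c in sorted(self._grid)]

    def n_objects(self) -> int:
        return len(self._grid)

    def cells(self) -> Iterator[tuple[Cell, Optional[ObjectSpec]]]:
        for r in range(1, self.n_rows + 1):
            for c in range(1, self.n_cols + 1):
                yield (r, c), self._grid.get((r, c))

    # -- line access (rows / columns) --------------------------------------
    def row(self, r: int) -> list[ObjectSpec]:
        return [self._grid[(r, c)] for c in range(1, self.n_cols + 1) if (r, c) in self._grid]

    def column(self, c: int) -> list[ObjectSpec]:
        return [self._grid[(r, c)] for r in range(1, self.n_rows + 1) if (r, c) in self._grid]

    # -- moves -------------------------------------------------------------
    def is_legal(self, move: Move) -> bool:
        return move.from_cell in self._grid and move.to_cell not in self._grid and (
            1 <= move.to_cell[0] <= self.n_rows and 1 <= move.to_cell[1] <= self.n_cols
        )

    def apply(self, move: Move) -> "ShelfState":
        if not self.is_legal(move):
            raise ValueError(f"illegal move {move} on this state")
        grid = dict(self._grid)
        grid[move.to_cell] = grid.pop(move.from_cell)
        return ShelfState(grid, self.n_rows, self.n_cols)

    # -- identity ----------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        return isinstance(other, ShelfState) and self._key == other._key and (
            self.n_rows == other.n_rows and self.n_cols == other.n_cols
        )

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        rows = []
        for r in range(1, self.n_rows + 1):
            cells = []
            for c in range(1, self.n_cols + 1):
                obj = self._grid.get((r, c))
                cells.append("." * 6 if obj is None else f"{obj.color[0]}{obj.shape[:2]}")
            rows.append(" ".join(f"{x:6s}" for x in cells))
        return "\n".join(rows)


def generate_initial_configuration(
    rng: np.random.Generator, n_objects: int = 16, n_rows: int = 5, n_cols: int = 5
) -> ShelfState:
    """Place objects uniformly at random on distinct cells of an empty shelf.

    With the default ``n_objects=16`` the full inventory (every color x shape
    pair once) is used; with fewer objects a random subset is drawn.

    Raises
    ------
    ValueError
        If ``n_objects`` exceeds the shelf capacity or the 16-object
        inventory.
    """
    capacity = n_rows * n_cols
    if n_objects > capacity:
        raise ValueError(f"cannot place {n_objects} objects on {capacity} cells")
    inventory = all_objects()
    if n_objects > len(inventory):
        raise ValueError(f"only {len(inventory)} distinct objects exist")
    objs = inventory if n_objects == len(inventory) else [
        inventory[i] for i in rng.choice(len(inventory), size=n_objects, replace=False)
    ]
    cells = [(r, c) for r in range(1, n_rows + 1) for c in range(1, n_cols + 1)]
    chosen = rng.choice(capacity, size=n_objects, replace=False)
    return ShelfState({cells[i]: obj for i, obj in zip(chosen, objs)}, n_rows, n_cols)


@dataclass(frozen=True)
class ShelfGeometry:
    """Physical layout of the shelf and the observer's viewpoint.

    The shelf front is a ``width`` x ``height`` plane centered at eye level,
    ``distance`` meters in front of the observer along +z.  Cell centers are
    on a regular grid; row 1 is the top row (largest y).
    """

    width: float = 2.0
    height: float = 2.0
    distance: float = 1.5
    n_rows: int = 5
    n_cols: int = 5

    def cell_center(self, cell: Cell) -> np.ndarray:
        """World-space center of a cell (x right, y up, z forward)."""
        r, c = cell
        if not (1 <= r <= self.n_rows and 1 <= c <= self.n_cols):
            raise ValueError(f"cell {cell} outside shelf")
        x = (c - (self.n_cols + 1) / 2) * (self.width / self.n_cols)
        y = -(r - (self.n_rows + 1) / 2) * (self.height / self.n_rows)
        return np.array([x, y, self.distance])

    def cell_direction(self, cell: Cell) -> np.ndarray:
        """Unit gaze direction from the observer to a cell center."""
        p = self.cell_center(cell)
        return p / np.linalg.norm(p)

    def all_cells(self) -> list[Cell]:
        return [(r, c) for r in range(1, self.n_rows + 1) for c in range(1, self.n_cols + 1)]

    def nearest_cell_to_direction(self, direction: np.ndarray) -> tuple[Cell, float]:
        """Nearest cell by angular distance; returns (cell, angle in degrees)."""
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        best, best_ang = None, np.inf
        for cell in self.all_cells():
            cd = self.cell_direction(cell)
            ang = np.degrees(np.arccos(np.clip(d @ cd, -1.0, 1.0)))
            if ang < best_ang:
                best, best_ang = cell, ang
        return best, best_ang

    def nearest_cell_to_position(self, pos: np.ndarray) -> tuple[Cell, float]:
        """Nearest cell center to a world position; returns (cell, distance m)."""
        p = np.asarray(pos, dtype=float)
        best, best_d = None, np.inf
        for cell in self.all_cells():
            d = float(np.linalg.norm(p - self.cell_center(cell)))
            if d < best_d:
                best, best_d = cell, d
        return best, best_d

    @property
    def cell_pitch_deg(self) -> float:
        """Approximate angular pitch between adjacent cell centers (degrees)."""
        pitch_m = self.width / self.n_cols
        return float(np.degrees(np.arctan2(pitch_m, self.distance)))
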