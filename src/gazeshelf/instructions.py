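"""The twelve sorting instructions: goal predicates and configuration scores.

Eight EASY instructions sort by a single feature along rows or columns
("each row has the same color or is empty", "each column has all unique
shapes or is empty", ...).  Four HARD instructions demand Latin-square-like
arrangements ("each row has all the unique colors and all the unique shapes
once", "each row and column has each of the four colors once", ...).

Goal predicates are line-wise.  A line (row or column) satisfies a
"same"-mode rule when all its occupied cells share the required feature
value; it satisfies a "unique"/"latin"-mode rule when no required feature
value repeats within the line.  Empty lines always satisfy: with 16 objects
on a 5x5 shelf every goal arrangement necessarily leaves lines empty.

A configuration score measures progress toward the goal and drives the
greedy task model:

* same-mode lines score the count of the modal feature value among occupied
  cells ("the number of identical object features"); an empty line scores 0.
* unique/latin-mode lines score the number of feature values appearing
  exactly once in the line ("the number of unique object features"), summed
  over the required features (colors + shapes for the two-feature HARD
  instructions).
* Instructions over both axes sum the line scores over rows and columns.

The total score is the sum over lines, and is maximal exactly at the goal
states for the given object multiset.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .shelf import COLORS, SHAPES, Cell, ShelfState

TrialType = str  # "EASY" | "HARD"


@dataclass(frozen=True)
class Instruction:
    """One sorting instruction.

    ``axis``: which lines the rule applies to ("row", "column", "both").
    ``feature``: the feature(s) the rule mentions ("color", "shape", "both").
    ``mode``: "same" (all occupied cells in a line share the feature) or
    "unique"/"latin" (no required feature value repeats within a line;
    "latin" marks the HARD variants that demand it for two features or for
    both axes at once).
    """

    id: str
    trial_type: TrialType
    axis: str
    feature: str
    mode: str
    text: str

    def features(self) -> tuple[str, ...]:
        return ("color", "shape") if self.feature == "both" else (self.feature,)

    def axes(self) -> tuple[str, ...]:
        return ("row", "column") if self.axis == "both" else (self.axis,)


def _mk(id_, trial_type, axis, feature, mode, text):
    return Instruction(id_, trial_type, axis, feature, mode, text)


INSTRUCTIONS: dict[str, Instruction] = {
    i.id: i
    for i in [
        _mk("easy_row_same_shape", "EASY", "row", "shape", "same",
            "Sort objects so that each row has the same shape or is empty"),
        _mk("easy_row_unique_shape", "EASY", "row", "shape", "unique",
            "Sort objects so that each row has all unique shapes or is empty"),
        _mk("easy_row_same_color", "EASY", "row", "color", "same",
            "Sort objects so that each row has the same color or is empty"),
        _mk("easy_row_unique_color", "EASY", "row", "color", "unique",
            "Sort objects so that each row has all unique colors or is empty"),
        _mk("easy_col_same_shape", "EASY", "column", "shape", "same",
            "Sort objects so that each column has the same shape or is empty"),
        _mk("easy_col_unique_shape", "EASY", "column", "shape", "unique",
            "Sort objects so that each column has all unique shapes or is empty"),
        _mk("easy_col_same_color", "EASY", "column", "color", "same",
            "Sort objects so that each column has the same color or is empty"),
        _mk("easy_col_unique_color", "EASY", "column", "color", "unique",
            "Sort objects so that each column has all unique colors or is empty"),
        _mk("hard_row_latin_both", "HARD", "row", "both", "latin",
            "Sort objects so that each row has all the unique colors and all the unique shapes once"),
        _mk("hard_col_latin_both", "HARD", "column", "both", "latin",
            "Sort objects so that each column has all the unique colors and all the unique shapes once"),
        _mk("hard_rowcol_latin_color", "HARD", "both", "color", "latin",
            "Sort objects so that each row and column has each of the four colors once"),
        _mk("hard_rowcol_latin_shape", "HARD", "both", "shape", "latin",
            "Sort objects so that each row and column has each of the four shapes once"),
    ]
}

EASY_INSTRUCTIONS = [i for i in INSTRUCTIONS.values() if i.trial_type == "EASY"]
HARD_INSTRUCTIONS = [i for i in INSTRUCTIONS.values() if i.trial_type == "HARD"]


# ---------------------------------------------------------------------------
# Fast line-based core.  The solver calls these with a plain dict mapping
# cell -> feature-code (color_index * len(SHAPES) + shape_index).

def object_code(color: str, shape: str) -> int:
    return COLORS.index(color) * len(SHAPES) + SHAPES.index(shape)


def line_cells(axis: str, n_rows: int, n_cols: int) -> list[list[Cell]]:
    """Cells of every line along one axis ('row' or 'column')."""
    if axis == "row":
        return [[(r, c) for c in range(1, n_cols + 1)] for r in range(1, n_rows + 1)]
    if axis == "column":
        return [[(r, c) for r in range(1, n_rows + 1)] for c in range(1, n_cols + 1)]
    raise ValueError(axis)


def instruction_lines(instruction: Instruction, n_rows: int, n_cols: int) -> list[list[Cell]]:
    lines: list[list[Cell]] = []
    for ax in instruction.axes():
        lines.extend(line_cells(ax, n_rows, n_cols))
    return lines


def _feature_values(codes: list[int], feature: str) -> list[int]:
    n = len(SHAPES)
    return [v // n for v in codes] if feature == "color" else [v % n for v in codes]


def line_score(codes: list[int], instruction: Instruction) -> int:
    """Score of one line given the feature codes of its occupied cells.

    Same-mode: count of the modal value.  Unique/latin-mode: count of
    values occurring exactly once, summed over required features.
    """
    if not codes:
        return 0
    total = 0
    for feat in instruction.features():
        counts = Counter(_feature_values(codes, feat))
        if instruction.mode == "same":
            total += max(counts.values())
        else:
            total += sum(1 for k in counts.values() if k == 1)
    return total


def line_satisfied(codes: list[int], instruction: Instruction) -> bool:
    """Goal predicate for one line (empty lines always satisfy)."""
    if not codes:
        return True
    for feat in instruction.features():
        vals = _feature_values(codes, feat)
        if instruction.mode == "same":
            if len(set(vals)) > 1:
                return False
        else:  # unique / latin: no repeated value
            if len(set(vals)) != len(vals):
                return False
    return True


def score_grid(grid: dict[Cell, int], lines: list[list[Cell]], instruction: Instruction) -> int:
    total = 0
    for cells in lines:
        codes = [grid[c] for c in cells if c in grid]
        total += line_score(codes, instruction)
    return total


def goal_grid(grid: dict[Cell, int], lines: list[list[Cell]], instruction: Instruction) -> bool:
    for cells in lines:
        codes = [grid[c] for c in cells if c in grid]
        if not line_satisfied(codes, instruction):
            return False
    return True


# ---------------------------------------------------------------------------
# Public ShelfState-level interface.

def _state_grid(state: ShelfState) -> dict[Cell, int]:
    return {cell: object_code(obj.color, obj.shape) for cell, obj in state.cells() if obj is not None}


def score_configuration(state: ShelfState, instruction: Instruction) -> int:
    """Total configuration score of a shelf state under an instruction."""
    lines = instruction_lines(instruction, state.n_rows, state.n_cols)
    return score_grid(_state_grid(state), lines, instruction)


def is_goal(state: ShelfState, instruction: Instruction) -> bool:
    """Whether a shelf state satisfies the instruction's goal predicate.

    Empty lines are always acceptable: with 16 objects on a 5x5 shelf every
    goal arrangement necessarily leaves at least one row (and, for the
    row-and-column instructions, one column) empty.
    """
    lines = instruction_lines(instruction, state.n_rows, state.n_cols)
    return goal_grid(_state_grid(state), lines, instruction)
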