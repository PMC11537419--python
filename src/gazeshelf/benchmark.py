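"""Greedy-model benchmark over simulated cohorts.

Reproduces the model side of the human-vs-model comparison: a cohort of
simulated subjects each receives 16 EASY trials (the 8 EASY instruction
subtypes twice) and 8 HARD trials (the 4 HARD subtypes twice) with
uniformly random initial placements of the 16 objects; the greedy model
is run on every trial, unconstrained and with the bottom-row /
rightmost-column drop-off constraint.  Reported statistics are grand
means of the per-subject mean displacement counts over solved trials,
and the percentage of trials the constrained model cannot solve.
"""

from __future__ import annotations

import numpy as np

from .instructions import EASY_INSTRUCTIONS, HARD_INSTRUCTIONS
from .shelf import generate_initial_configuration
from .solver import greedy_solve


def model_benchmark(
    n_subjects: int = 48,
    seed: int | np.random.Generator = 0,
    method: str = "stack",
) -> dict:
    """Run the greedy model over a full simulated cohort.

    Returns a dict with grand means ``easy_mean``, ``hard_mean``,
    ``easy_constrained_mean``, ``hard_constrained_mean``, unsolvable
    percentages per condition, and the trial counts used.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conditions = {
        ("EASY", False): [], ("EASY", True): [],
        ("HARD", False): [], ("HARD", True): [],
    }
    unsolved = {k: [0, 0] for k in conditions}   # [unsolved, total]

    for _ in range(n_subjects):
        per_subj = {k: [] for k in conditions}
        trials = [(ins, "EASY") for ins in EASY_INSTRUCTIONS for _ in range(2)]
        trials += [(ins, "HARD") for ins in HARD_INSTRUCTIONS for _ in range(2)]
        for ins, ttype in trials:
            state = generate_initial_configuration(rng)
            for constrained in (False, True):
                res = greedy_solve(state, ins, constrained=constrained, method=method)
                key = (ttype, constrained)
                unsolved[key][1] += 1
                if res.solved:
                    per_subj[key].append(res.n_moves)
                else:
                    unsolved[key][0] += 1
        for key, vals in per_subj.items():
            if vals:
                conditions[key].append(float(np.mean(vals)))

    def grand(key):
        return float(np.mean(conditions[key])) if conditions[key] else float("nan")

    def pct(key):
        u, n = unsolved[key]
        return 100.0 * u / n if n else float("nan")

    return {
        "easy_mean": grand(("EASY", False)),
        "hard_mean": grand(("HARD", False)),
        "easy_constrained_mean": grand(("EASY", True)),
        "hard_constrained_mean": grand(("HARD", True)),
        "easy_unsolvable_pct": pct(("EASY", False)),
        "hard_unsolvable_pct": pct(("HARD", False)),
        "easy_constrained_unsolvable_pct": pct(("EASY", True)),
        "hard_constrained_unsolvable_pct": pct(("HARD", True)),
        "n_subjects": n_subjects,
        "n_easy_trials": n_subjects * 16,
        "n_hard_trials": n_subjects * 8,
        "method": method,
    }
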