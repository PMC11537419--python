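#!/usr/bin/env python
"""Gaze transition asymmetry and first-fixation latencies, with their
mixed models.

Computes per-trial relative net transitions (asymmetric vs total ROI
transition flow) for preparation and execution epochs and fits the
trial-type x epoch-type mixed model; computes normalized first-fixation
latencies per ROI and fits the preparation- and execution-epoch latency
models against the current-target-object reference.

Writes results/transitions.csv, results/transitions_lmm.csv,
results/latencies.csv, results/latency_prep_lmm.csv and
results/latency_exec_lmm.csv.
"""

from pathlib import Path

import pandas as pd

from gazeshelf import (
    AgentPolicy, GeneratorConfig, first_fixation_latencies, fit_and_report,
    process_sessions, simulate_session, transitions_table,
)
from gazeshelf.mixed import MODEL_SPECS

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 11


def main():
    OUT.mkdir(exist_ok=True)
    sessions = simulate_session(GeneratorConfig(), n_subjects=6,
                                policy=AgentPolicy("spatial_heuristic"), seed=SEED)
    out = process_sessions(sessions)

    trans = transitions_table(out["fixations"])
    trans.to_csv(OUT / "transitions.csv", index=False)
    print("Mean relative net transitions:")
    print(trans.groupby(["trial_type", "epoch_kind"]).relative_net_transitions
          .mean().round(3).to_string())
    rep = fit_and_report(trans, MODEL_SPECS["transitions"])
    rep.table.to_csv(OUT / "transitions_lmm.csv", index=False)
    print("\n" + str(rep))

    lat = first_fixation_latencies(out["epochs"], out["fixations"])
    lat.to_csv(OUT / "latencies.csv", index=False)
    cur = lat[lat.roi == "cur_target_object"]
    print("\nMean normalized latency of the first current-target-object fixation:")
    print(cur.groupby(["trial_type", "epoch_kind"]).latency.mean().round(3).to_string())
    for name in ("latency_prep", "latency_exec"):
        rep = fit_and_report(lat, MODEL_SPECS[name])
        rep.table.to_csv(OUT / f"{name}_lmm.csv", index=False)
        print("\n" + str(rep))


if __name__ == "__main__":
    main()
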