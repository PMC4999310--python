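#!/usr/bin/env python
"""Simulate human-like and rat-like multi-condition quantal experiments.

Generates one cohort of synthetic paired-recording experiments per
species-like parameter set (4 calcium conditions, 75 trials per epoch) and
writes the trial tables under results/. These tables feed the MPFA driver
(03) and demonstrate the CSV schema consumed by the `fit` CLI.
"""

from pathlib import Path

import pandas as pd

from synquant import io, simulate
from synquant.types import Condition, QuantalParameters

RESULTS = Path(__file__).resolve().parent.parent / "results"

# human-like: many sites, q ~ 40 fC; rat-like: few sites, q ~ 30 fC;
# P_r ladders follow the reported per-condition estimates
COHORTS = {
    "human_like": (
        QuantalParameters(n_sites=20, q_fc=40.0, cv_intra=0.3),
        [Condition("ca0.5", 0.5, 0.10), Condition("ca1.5", 1.5, 0.33),
         Condition("ca2.0", 2.0, 0.50), Condition("ca4.0", 4.0, 0.80)],
    ),
    "rat_like": (
        QuantalParameters(n_sites=5, q_fc=30.0, cv_intra=0.3),
        [Condition("ca1.0", 1.0, 0.08), Condition("ca1.5", 1.5, 0.17),
         Condition("ca2.0", 2.0, 0.30), Condition("ca4.0", 4.0, 0.60)],
    ),
}

N_EXPERIMENTS = 4
N_TRIALS = 75


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for name, (params, conditions) in COHORTS.items():
        frames = []
        for i in range(N_EXPERIMENTS):
            exp = simulate.make_experiment(params, conditions, N_TRIALS,
                                           seed=1000 + i)
            frames.append(io.experiment_to_frame(exp, f"{name}_{i:02d}"))
        table = pd.concat(frames, ignore_index=True)
        out = RESULTS / f"trials_{name}.csv"
        table.to_csv(out, index=False, float_format="%.4f")
        print(f"{name}: {N_EXPERIMENTS} experiments x "
              f"{len(conditions)} epochs x {N_TRIALS} trials -> {out}")


if __name__ == "__main__":
    main()
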