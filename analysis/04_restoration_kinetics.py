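#!/usr/bin/env python
"""Restoration-kinetics classification and its recovery of simulated truth.

Runs the full measurement pipeline (extend -> bin -> RRPM -> peak windows ->
earliest-timepoint-at-final-level classifier -> replicate concordance) on a
two-replicate simulated chase (T0/T1/T6/T12) with balanced true plateau
categories, then scores the calls against the simulator's ground truth.

Writes results/restoration_proportions.tsv and results/restoration_recovery.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from chorseq.studies import run_restoration_recovery


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    r = run_restoration_recovery(args.seed)
    pd.DataFrame(
        {
            "category": list(r.proportions),
            "recovered_proportion": list(r.proportions.values()),
            "true_proportion": [r.true_proportions[k] for k in r.proportions],
        }
    ).to_csv(args.out / "restoration_proportions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            ("n_windows", r.n_windows),
            ("n_concordant", r.n_concordant),
            ("retained_fraction", round(r.retained_fraction, 4)),
            ("accuracy_concordant", round(r.accuracy, 4)),
            ("max_proportion_error", round(r.max_proportion_error, 4)),
            ("rrpm_final_t0_ratio", round(r.rrpm_final_t0_ratio, 4)),
            ("rpm_final_t0_ratio", round(r.rpm_final_t0_ratio, 4)),
        ],
        columns=["quantity", "value"],
    ).to_csv(args.out / "restoration_recovery.tsv", sep="\t", index=False)

    print(f"{r.n_windows} replicated peak windows; "
          f"{r.n_concordant} concordant across replicates "
          f"({r.retained_fraction:.1%}).")
    print(f"Concordant-call accuracy vs truth: {r.accuracy:.1%}; "
          f"max category-proportion error "
          f"{100*r.max_proportion_error:.2f} points.")
    print("Recovered proportions: "
          + ", ".join(f"{k}={v:.1%}" for k, v in r.proportions.items()))
    print(f"-> {args.out/'restoration_proportions.tsv'}")


if __name__ == "__main__":
    main()
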