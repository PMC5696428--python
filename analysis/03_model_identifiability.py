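#!/usr/bin/env python
"""Can BIC recover the generating flight-time family under each logger?

Every simulated record is fit with all four candidate families under the
exact multinomial likelihood; models are ranked by BIC and the
BIC-approximate model probabilities are averaged per generator cell.

Finding: at 10 s the generating family dominates the average model
probability.  At 1 h the gamma remains identifiable, while for this
emulator the exponential also remains identifiable at 1 h: uniform-phase
aggregation of memoryless flights yields an exactly geometric record, which
the exponential family fits perfectly at every interval.
"""

import argparse
import os

import flightfit as ff
from flightfit.experiments import StudyConfig, summarize_selection


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--full", action="store_true",
                    help="full design: 4 scales, 10 reps of 3,000 flights")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    cfg = StudyConfig(base_seed=args.seed)
    if not args.full:
        cfg = StudyConfig(scale_targets=(1.0,), n_flights=1000, n_reps=3,
                          base_seed=args.seed)
    rows = ff.run_model_identifiability(cfg)
    summ = summarize_selection(rows)

    os.makedirs(args.out, exist_ok=True)
    rows.to_csv(os.path.join(args.out, "model_identifiability_fits.csv"), index=False)
    summ.to_csv(os.path.join(args.out, "model_identifiability_summary.csv"),
                index=False)

    table = summ.pivot_table(index=["family", "scale_target", "scheme"],
                             columns="fitted_family", values="mean_prob")
    print("average model probability (rows: generator cell):")
    print(table.round(3).to_string())
    share = summ[summ["family"] == summ["fitted_family"]]
    print("\nselection share of the generating family per cell:")
    print(share.set_index(["family", "scale_target", "scheme"])
          ["selection_share"].round(2).to_string())


if __name__ == "__main__":
    main()
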