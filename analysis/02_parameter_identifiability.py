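#!/usr/bin/env python
"""Back-estimate generator parameters under each logger's observation scheme.

For every simulated record the generating family is refit with both the naive
likelihood (observed lengths treated as exact durations) and the exact
multinomial likelihood that models aggregation and truncation; estimates are
compared against the known truth.

Finding: at 10 s sampling the exact-likelihood estimates sit within a few
percent of truth for every family; at 1 h aggregation the errors inflate by
an order of magnitude once the flight scale is at or below the interval.
"""

import argparse
import os

import flightfit as ff
from flightfit.experiments import StudyConfig, summarize_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--full", action="store_true",
                    help="full design: 4 scales, 10 reps of 3,000 flights")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    cfg = StudyConfig(base_seed=args.seed)
    if not args.full:
        cfg = StudyConfig(scale_targets=(0.5, 1.0), n_flights=1000, n_reps=3,
                          base_seed=args.seed)
    rows = ff.run_parameter_identifiability(cfg)
    summ = summarize_study(rows)

    os.makedirs(args.out, exist_ok=True)
    rows.to_csv(os.path.join(args.out, "param_identifiability_fits.csv"), index=False)
    summ.to_csv(os.path.join(args.out, "param_identifiability_summary.csv"), index=False)

    med = summ.pivot_table(index=["family", "scale_target", "param"],
                           columns=["scheme", "method"],
                           values="median_abs_rel_error")
    print("median |relative error| by scheme and method:")
    print(med.round(3).to_string())


if __name__ == "__main__":
    main()
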