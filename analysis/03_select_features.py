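#!/usr/bin/env python
"""Feature-selection phase: feature number by CV simulation, RFE frequency
voting, and correlation pruning.

Normalizes the training split (z-scores fit on training cases only),
determines the feature count 1..10 by the 4-subgroup x 5-repeat
cross-validated simulation, votes features over 5 repeated RFE runs per
sequence, prunes |r| > 0.7 pairs, and writes the selection report.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from sbradiomics.features import read_feature_table, split_xy, zscore_fit_apply
from sbradiomics.pipeline import FAST_RFE_STEP
from sbradiomics.selection import SelectionConfig, run_selection


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", type=Path, default=Path("scratch/features.csv"))
    ap.add_argument("--split", type=Path, default=Path("results/cohort_split.csv"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--k", type=int, default=None,
                    help="fixed per-sequence feature number (default: determine by CV)")
    ap.add_argument("--out", type=Path, default=Path("results/selection.json"))
    args = ap.parse_args()

    table = read_feature_table(args.features)
    split = pd.read_csv(args.split, index_col="case_id")
    train = table.loc[split.index[split["split"] == "train"]]
    X_train, y_train = split_xy(train)
    (X_norm,), _ = zscore_fit_apply(X_train)

    config = SelectionConfig(seed=args.seed, rfe_step=FAST_RFE_STEP)
    result = run_selection(X_norm, y_train, config, k=args.k)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)

    print(f"feature number: {result.chosen_k} per sequence")
    n_dropped = len(result.selected) - len(result.pruned)
    print(f"voted {len(result.selected)} features, pruned {n_dropped} "
          f"correlated (|r| > 0.7), kept {len(result.pruned)}:")
    for name in result.pruned:
        print(f"  {name}  (frequency {result.frequencies.get(name, 0)}/5)")
    print(f"report -> {args.out}")


if __name__ == "__main__":
    main()
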