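#!/usr/bin/env python
"""Simulate a two-class MRI-like cohort and write it as NIfTI + manifest.

Generates paired GdT1/T2-role phantom volumes with ellipsoidal tumor VOIs
(two classes differing in texture correlation length and mean intensity),
splits them chronologically into training and final-validation sets, and
writes the volumes under a scratch directory with a manifest and split
table under results/.
"""

import argparse
import csv
from pathlib import Path

from sbradiomics.synthetic import CohortConfig, generate_cohort, write_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-train", type=int, default=20, help="training cases per class")
    ap.add_argument("--n-val", type=int, default=5, help="validation cases per class")
    ap.add_argument("--effect-size", type=float, default=1.5)
    ap.add_argument("--scratch", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    config = CohortConfig(
        n_cases_per_class=args.n_train + args.n_val,
        effect_size=args.effect_size,
        seed=args.seed,
    )
    cases = generate_cohort(config)
    manifest = write_cohort(cases, args.scratch)

    # chronological split per class: the last n_val cases are held out
    per_class_seen = {0: 0, 1: 0}
    args.results.mkdir(parents=True, exist_ok=True)
    split_path = args.results / "cohort_split.csv"
    with open(split_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["case_id", "label", "split"])
        for case in cases:
            split = "train" if per_class_seen[case.label] < args.n_train else "validation"
            per_class_seen[case.label] += 1
            w.writerow([case.case_id, case.label, split])

    sizes = [c.mask.voxel_count for c in cases]
    vol_cm3 = [c.mask.voxel_count * c.mask.voxel_volume / 1000 for c in cases]
    print(f"wrote {len(cases)} cases ({args.n_train}+{args.n_val} per class) to {args.scratch}")
    print(f"manifest: {manifest}")
    print(f"split table: {split_path}")
    print(f"VOI sizes: {min(sizes)}-{max(sizes)} voxels "
          f"({min(vol_cm3):.1f}-{max(vol_cm3):.1f} cm^3), effect size {args.effect_size}")


if __name__ == "__main__":
    main()
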