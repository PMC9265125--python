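#!/usr/bin/env python
"""Model-selection and test phases: grid-searched logistic regression and
SVM with repeated 5-fold AUC, then the hold-out test.

For each learner, tunes hyperparameters by grid search with nested 2-fold
CV on 80% of the training cases, evaluates by stratified repeated 5-fold
CV (mean +/- SD AUC), refits on all training cases, and scores the
disjoint validation split. Writes the model report and ROC points.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from sbradiomics.features import read_feature_table, split_xy
from sbradiomics.modeling import ModelConfig, evaluate_cv, test_holdout, tune
from sbradiomics.features import zscore_fit_apply


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", type=Path, default=Path("scratch/features.csv"))
    ap.add_argument("--split", type=Path, default=Path("results/cohort_split.csv"))
    ap.add_argument("--selection", type=Path, default=Path("results/selection.json"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/model_report.json"))
    args = ap.parse_args()

    table = read_feature_table(args.features)
    split = pd.read_csv(args.split, index_col="case_id")
    feats = json.loads(args.selection.read_text())["pruned"]
    train = table.loc[split.index[split["split"] == "train"]]
    val = table.loc[split.index[split["split"] == "validation"]]
    X_train, y_train = split_xy(train)
    X_val, y_val = split_xy(val)

    report = {"selected_features": feats, "seed": args.seed, "models": {}}
    roc_rows = []
    for learner in ("logistic_regression", "svm"):
        cfg = ModelConfig(learner=learner, seed=args.seed)
        (X_tune,), _ = zscore_fit_apply(X_train[feats])
        params = tune(X_tune, y_train, cfg)
        ev = evaluate_cv(X_train[feats], y_train, cfg, params)
        acc, frac, pred = test_holdout(
            X_train[feats], y_train, X_val[feats], y_val, cfg, params
        )
        report["models"][learner] = {
            "params": params,
            "cv_mean_auc": ev.mean_auc,
            "cv_sd_auc": ev.sd_auc,
            "fold_aucs": ev.fold_aucs,
            "holdout_accuracy": acc,
            "holdout_fraction": str(frac),
            "holdout_predictions": {str(i): int(p) for i, p in pred.items()},
        }
        for fold, curve in enumerate(ev.roc_curves):
            for fpr, tpr in zip(curve["fpr"], curve["tpr"]):
                roc_rows.append((learner, fold, fpr, tpr))
        print(f"{learner}: params {params}; CV AUC "
              f"{ev.mean_auc:.2f} +/- {ev.sd_auc:.2f}; hold-out accuracy "
              f"{acc:.2f} ({frac})")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(report, fh, indent=2)
    roc_path = args.out.parent / "roc_points.csv"
    pd.DataFrame(roc_rows, columns=["learner", "fold", "fpr", "tpr"]).to_csv(
        roc_path, index=False
    )
    print(f"report -> {args.out}; ROC points -> {roc_path}")


if __name__ == "__main__":
    main()
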