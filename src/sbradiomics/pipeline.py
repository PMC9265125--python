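"""End-to-end driver: extract -> normalize -> select -> tune -> evaluate
-> hold-out test on a train/validation cohort split.

This is the whole analysis chained with leak-safe defaults: z-score and
selection statistics come from the training split only, and the hold-out
model is refit on all training cases with the tuned hyperparameters. For
very wide feature tables the RFE inside selection uses a geometric
elimination schedule (drop 20% of the remaining columns per refit until 30
remain, then one at a time); pass ``rfe_step=1`` for strict one-at-a-time
elimination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import extract_cohort, split_xy, zscore_fit_apply
from .modeling import EvalReport, ModelConfig, evaluate_cv, test_holdout, tune
from .selection import SelectionConfig, SelectionResult, run_selection
from .synthetic import CohortConfig, SyntheticCase, generate_cohort

#: geometric RFE schedule used by default on wide tables
FAST_RFE_STEP = 0.2


@dataclass
class PipelineReport:
    selection: SelectionResult
    params: dict
    evaluation: EvalReport
    holdout_accuracy: float
    holdout_fraction: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "selection": self.selection.to_dict(),
            "params": self.params,
            "evaluation": self.evaluation.to_dict(),
            "holdout_accuracy": self.holdout_accuracy,
            "holdout_fraction": self.holdout_fraction,
            "seed": self.seed,
        }


def run_pipeline(
    train_table: pd.DataFrame,
    val_table: pd.DataFrame,
    k: int | None = 5,
    learner: str = "logistic_regression",
    seed: int = 0,
    rfe_step: float = FAST_RFE_STEP,
    determine_k: bool = False,
) -> PipelineReport:
    """Run selection, tuning, CV evaluation and the hold-out test.

    ``k`` is the per-sequence feature count; with ``determine_k`` it is
    instead chosen by the 4-subgroup x 5-repeat CV simulation.
    """
    X_train, y_train = split_xy(train_table)
    X_val, y_val = split_xy(val_table)
    (X_train_n, X_val_n), _ = zscore_fit_apply(X_train, X_val)
    sel_config = SelectionConfig(seed=seed, rfe_step=rfe_step)
    selection = run_selection(
        X_train_n, y_train, sel_config, k=None if determine_k else k
    )
    feats = selection.pruned
    model_config = ModelConfig(learner=learner, seed=seed)
    params = tune(X_train_n[feats], y_train, model_config)
    evaluation = evaluate_cv(
        X_train[feats], y_train, model_config, params, normalize=True
    )
    acc, frac, pred = test_holdout(
        X_train[feats], y_train, X_val[feats], y_val, model_config, params
    )
    evaluation.holdout_accuracy = acc
    evaluation.holdout_fraction = str(frac)
    evaluation.holdout_predictions = {str(i): int(p) for i, p in pred.items()}
    return PipelineReport(
        selection=selection,
        params=params,
        evaluation=evaluation,
        holdout_accuracy=acc,
        holdout_fraction=str(frac),
        seed=seed,
    )


def simulate_and_run(
    n_train_per_class: int | tuple[int, int],
    n_val_per_class: int | tuple[int, int],
    cohort_kwargs: dict,
    seed: int = 0,
    **pipeline_kwargs,
) -> PipelineReport:
    """Generate a synthetic train+validation cohort and run the pipeline.

    Training and validation cases come from one generator call (validation
    cases are the last ones per class, mimicking a chronological split), so
    the two sets share the generating process but no noise draws. Per-class
    counts may be a pair to emulate an imbalanced cohort (e.g. 27 vs 20
    training cases); surplus generated cases are simply not extracted.
    """
    n_train = (n_train_per_class,) * 2 if np.isscalar(n_train_per_class) else tuple(
        n_train_per_class)
    n_val = (n_val_per_class,) * 2 if np.isscalar(n_val_per_class) else tuple(
        n_val_per_class)
    config = CohortConfig(
        n_cases_per_class=max(t + v for t, v in zip(n_train, n_val)),
        seed=seed,
        **cohort_kwargs,
    )
    cases = generate_cohort(config)
    by_class: dict[int, list[SyntheticCase]] = {0: [], 1: []}
    for case in cases:
        by_class[case.label].append(case)
    train = [c for lab in (0, 1) for c in by_class[lab][: n_train[lab]]]
    val = [
        c
        for lab in (0, 1)
        for c in by_class[lab][n_train[lab]: n_train[lab] + n_val[lab]]
    ]
    train_table = extract_cohort(train)
    val_table = extract_cohort(val)
    return run_pipeline(train_table, val_table, seed=seed, **pipeline_kwargs)
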