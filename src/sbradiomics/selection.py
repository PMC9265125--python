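"""Feature selection: LG-RFE, feature-number determination, frequency
voting and correlation pruning.

The selector is recursive feature elimination driven by an L2-regularized
logistic regression (C = 1) on z-scored features: at each step the model is
refit and the feature with the smallest absolute coefficient is removed.
The appropriate feature number (1..10) is chosen by a cross-validated
simulation: 4 stratified subgroups, 3 for fitting / 1 for validation,
repeated 5 times, picking the count with the highest mean accuracy (ties
break to the smaller count). The final feature set is voted over 5
repeated RFE runs on re-randomized 3/4 subsamples of the training cases,
keeping the most frequently surviving features, then pruned so that no
pair of same-sequence features has |Pearson r| > 0.7 (anticorrelated pairs
count as redundant too).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .features import sequence_of

#: regularization strength of the RFE logistic model
RFE_C = 1.0


def _logistic() -> LogisticRegression:
    # liblinear is L2-penalized by default; deterministic for fixed data
    return LogisticRegression(C=RFE_C, solver="liblinear", max_iter=200)


@dataclass
class SelectionConfig:
    """Feature-selection phase parameters."""

    candidate_feature_numbers: tuple[int, ...] = tuple(range(1, 11))
    n_subgroups: int = 4
    n_repeats: int = 5
    correlation_threshold: float = 0.7
    seed: int = 0
    rfe_step: float = 1  # 1 = strict one-at-a-time; <1 = geometric fraction

    def __post_init__(self) -> None:
        if not (0 < self.correlation_threshold < 1):
            raise ValueError("correlation threshold must be in (0, 1)")
        if self.n_subgroups < 2:
            raise ValueError("need at least 2 subgroups")


@dataclass
class RfeResult:
    """Survivors plus the order in which features were eliminated."""

    survivors: list[str]
    elimination_order: list[str]  # first entry was eliminated first

    def survivors_at(self, k: int) -> list[str]:
        """Survivor set at any k >= len(survivors) (elimination is nested)."""
        total = len(self.survivors) + len(self.elimination_order)
        if not (len(self.survivors) <= k <= total):
            raise ValueError(f"k={k} outside the recorded chain")
        n_restore = k - len(self.survivors)
        restored = self.elimination_order[len(self.elimination_order) - n_restore:]
        return restored + self.survivors


def rfe_rank(
    X: pd.DataFrame, y: np.ndarray, target_k: int, step: float = 1
) -> RfeResult:
    """Logistic-regression RFE down to ``target_k`` features.

    With the default ``step=1`` exactly one feature (the one with the
    smallest absolute coefficient; ties remove the lexicographically last
    name) is eliminated per refit, so survivor sets are nested across k.
    ``step<1`` eliminates that fraction of the remaining features per
    refit until 30 remain, then one at a time — a cheaper schedule for
    very wide tables.
    """
    if target_k < 1:
        raise ValueError("target_k must be >= 1")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: only one class present")
    cols = list(X.columns)
    if target_k > len(cols):
        raise ValueError(f"target_k={target_k} exceeds {len(cols)} columns")
    Xv = X.to_numpy(dtype=np.float64)
    col_idx = np.arange(len(cols))
    eliminated: list[str] = []
    clf = _logistic()
    while len(col_idx) > target_k:
        clf.fit(Xv[:, col_idx], y)
        importance = np.abs(clf.coef_[0])
        if step == 1 or len(col_idx) <= max(30, target_k):
            n_drop = 1
        else:
            n_drop = min(
                max(1, int(step * len(col_idx))), len(col_idx) - max(30, target_k)
            )
        order = np.argsort(importance, kind="stable")
        worst = order[:n_drop]
        if n_drop == 1:
            # tie-break: among minimal |coef|, drop the lexicographically last
            tied = np.flatnonzero(importance == importance[worst[0]])
            if len(tied) > 1:
                names = [cols[col_idx[t]] for t in tied]
                worst = np.array([tied[int(np.argmax(names))]])
        for w in sorted(worst, reverse=True):
            eliminated.append(cols[col_idx[w]])
        col_idx = np.delete(col_idx, worst)
    return RfeResult([cols[i] for i in col_idx], eliminated)


def determine_feature_number(
    X: pd.DataFrame, y: np.ndarray, config: SelectionConfig
) -> tuple[int, pd.DataFrame]:
    """Choose the feature count by the 4-subgroup x 5-repeat CV simulation.

    For every repeat, the training cases are split into 4 stratified
    subgroups; per subgroup held out, one RFE chain is run to the smallest
    candidate count on the remaining 3 subgroups and, for each candidate k,
    a logistic model on the k survivors is scored on the held-out subgroup.
    Returns (chosen k, accuracy table indexed by k with one column per
    repeat, fold-averaged); ties go to the smaller k.
    """
    y = np.asarray(y)
    if len(y) < 2 * config.n_subgroups:
        raise ValueError("too few cases for the subgroup split")
    ks = sorted(config.candidate_feature_numbers)
    acc = np.zeros((len(ks), config.n_repeats))
    for rep in range(config.n_repeats):
        skf = StratifiedKFold(
            n_splits=config.n_subgroups, shuffle=True, random_state=config.seed + rep
        )
        fold_acc = np.zeros((len(ks), config.n_subgroups))
        for fold, (tr, va) in enumerate(skf.split(X, y)):
            if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
                raise ValueError("a subgroup lost a class; use stratified data")
            chain = rfe_rank(X.iloc[tr], y[tr], min(ks), step=config.rfe_step)
            for i, k in enumerate(ks):
                feats = chain.survivors_at(k)
                clf = _logistic().fit(X.iloc[tr][feats], y[tr])
                fold_acc[i, fold] = clf.score(X.iloc[va][feats], y[va])
        acc[:, rep] = fold_acc.mean(axis=1)
    table = pd.DataFrame(
        acc, index=pd.Index(ks, name="n_features"),
        columns=[f"repeat_{r}" for r in range(config.n_repeats)],
    )
    mean_acc = table.mean(axis=1).to_numpy()
    chosen = ks[int(np.argmax(mean_acc))]  # argmax -> smallest k on ties
    return chosen, table


def select_by_frequency(
    X: pd.DataFrame,
    y: np.ndarray,
    k: int,
    n_repeats: int = 5,
    n_subgroups: int = 4,
    seed: int = 0,
    rfe_step: float = 1,
) -> tuple[list[str], pd.Series, dict]:
    """Frequency-voted RFE selection.

    Runs one RFE chain per repeat on a re-randomized stratified 3/4
    subsample of the cases, counts how often each feature survives to k,
    and returns the k most frequent features. Ties break by mean
    elimination rank (features eliminated later — or surviving — rank
    better), then lexicographically.

    Returns (selected features, per-feature frequencies in [1, n_repeats]
    for every feature that survived at least once, details with per-repeat
    survivor lists and mean elimination ranks).
    """
    y = np.asarray(y)
    n_cols = X.shape[1]
    freq: dict[str, int] = {}
    rank_sum = pd.Series(0.0, index=X.columns)
    survivor_sets = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_subgroups, shuffle=True,
                              random_state=seed + rep)
        _, holdout = next(iter(skf.split(X, y)))
        sub = np.setdiff1d(np.arange(len(y)), holdout)
        chain = rfe_rank(X.iloc[sub], y[sub], k, step=rfe_step)
        survivor_sets.append(chain.survivors)
        for name in chain.survivors:
            freq[name] = freq.get(name, 0) + 1
        # elimination rank: 1 = eliminated first; survivors share the top rank
        for r, name in enumerate(chain.elimination_order, start=1):
            rank_sum[name] += r
        for name in chain.survivors:
            rank_sum[name] += n_cols
    mean_rank = rank_sum / n_repeats
    candidates = sorted(
        freq, key=lambda n: (-freq[n], -mean_rank[n], n)
    )
    selected = candidates[:k]
    details = {
        "survivor_sets": survivor_sets,
        "mean_elimination_rank": mean_rank[candidates].to_dict(),
    }
    return selected, pd.Series(freq).sort_values(ascending=False), details


def prune_correlated(
    features: list[str],
    X: pd.DataFrame,
    threshold: float = 0.7,
    frequencies: pd.Series | None = None,
    importance: pd.Series | None = None,
) -> list[str]:
    """Remove redundant features until all same-sequence pairs have
    |Pearson r| <= threshold on the training table.

    While any pair exceeds the threshold, the member with the lower
    selection frequency is dropped (ties: lower mean importance, then the
    lexicographically later name). Correlations are computed within each
    sequence's features, mirroring per-sequence selection.
    """
    freq = frequencies if frequencies is not None else pd.Series(dtype=float)
    imp = importance if importance is not None else pd.Series(dtype=float)

    def _score(name: str) -> tuple:
        return (float(freq.get(name, 0.0)), float(imp.get(name, 0.0)))

    kept = list(features)
    while True:
        worst_pair = None
        worst_r = threshold
        by_seq: dict[str, list[str]] = {}
        for name in kept:
            by_seq.setdefault(sequence_of(name), []).append(name)
        for names in by_seq.values():
            if len(names) < 2:
                continue
            corr = X[names].corr().abs().to_numpy()
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.argmax(corr), corr.shape)
            if corr[i, j] > worst_r:
                worst_r = corr[i, j]
                worst_pair = (names[i], names[j])
        if worst_pair is None:
            return kept
        a, b = worst_pair
        if _score(a) < _score(b):
            drop = a
        elif _score(b) < _score(a):
            drop = b
        else:
            drop = max(a, b)  # lexicographically later name goes
        kept.remove(drop)


@dataclass
class SelectionResult:
    """Outcome of the full feature-selection phase."""

    chosen_k: int
    frequencies: dict[str, int]
    selected: list[str]
    pruned: list[str]
    accuracy_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "chosen_k": self.chosen_k,
            "frequencies": self.frequencies,
            "selected": self.selected,
            "pruned": self.pruned,
        }
        if self.accuracy_table is not None:
            out["accuracy_table"] = self.accuracy_table.to_dict()
        return out


def run_selection(
    X: pd.DataFrame,
    y: np.ndarray,
    config: SelectionConfig,
    k: int | None = None,
    per_sequence: bool = True,
) -> SelectionResult:
    """Full selection phase on a normalized training table.

    If ``k`` is None the feature number is determined by the CV simulation
    first. With ``per_sequence`` (default, mirroring per-sequence pairwise
    correlations) the voting runs independently on each sequence's columns
    and the union is pruned; otherwise selection is pooled.
    """
    acc_table = None
    if k is None:
        k, acc_table = determine_feature_number(X, y, config)
    groups: list[list[str]]
    if per_sequence:
        by_seq: dict[str, list[str]] = {}
        for name in X.columns:
            by_seq.setdefault(sequence_of(name), []).append(name)
        groups = [by_seq[s] for s in sorted(by_seq)]
    else:
        groups = [list(X.columns)]
    selected: list[str] = []
    freqs: dict[str, int] = {}
    for cols in groups:
        sel, fr, _ = select_by_frequency(
            X[cols], y, k, n_repeats=config.n_repeats,
            n_subgroups=config.n_subgroups, seed=config.seed,
            rfe_step=config.rfe_step,
        )
        selected += sel
        freqs.update({n: int(v) for n, v in fr.items()})
    pruned = prune_correlated(
        selected, X, config.correlation_threshold,
        frequencies=pd.Series(freqs, dtype=float),
    )
    return SelectionResult(k, freqs, selected, pruned, acc_table)
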