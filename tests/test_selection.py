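"""RFE ranking, feature-number determination, frequency voting and
correlation pruning."""

import numpy as np
import pandas as pd
import pytest

from sbradiomics.selection import (
    SelectionConfig,
    determine_feature_number,
    prune_correlated,
    rfe_rank,
    run_selection,
    select_by_frequency,
)


def _feature_name(i, seq="GD"):
    return f"-_{seq}_LLL_INT_f{i:03d}"


def planted_table(rng, n=50, n_features=50, n_informative=1, noise=0.3, seq="GD"):
    """Noise columns plus informative columns equal to the label + noise."""
    y = np.array([0, 1] * (n // 2))
    X = rng.standard_normal((n, n_features))
    for j in range(n_informative):
        X[:, j] = y + noise * rng.standard_normal(n)
    cols = [_feature_name(i, seq) for i in range(n_features)]
    return pd.DataFrame(X, columns=cols), y, cols[:n_informative]


def test_rfe_target_equals_width_is_identity():
    rng = np.random.default_rng(0)
    X, y, _ = planted_table(rng, n=20, n_features=8)
    res = rfe_rank(X, y, 8)
    assert res.survivors == list(X.columns)
    assert res.elimination_order == []


def test_rfe_survivor_chain_is_nested():
    rng = np.random.default_rng(1)
    X, y, _ = planted_table(rng, n=30, n_features=12)
    res = rfe_rank(X, y, 1)
    prev = set(res.survivors_at(1))
    for k in range(2, 13):
        cur = set(res.survivors_at(k))
        assert prev < cur
        prev = cur


def test_rfe_keeps_planted_feature():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X, y, planted = planted_table(rng)
        res = rfe_rank(X, y, 1)
        hits += res.survivors == planted
    assert hits >= 9


def test_rfe_identical_columns_tie_break():
    rng = np.random.default_rng(3)
    X, y, planted = planted_table(rng, n=40, n_features=10)
    X[_feature_name(1)] = X[planted[0]]  # exact duplicate of the signal
    res = rfe_rank(X, y, 1)
    assert len(res.survivors) == 1
    assert res.survivors[0] in {planted[0], _feature_name(1)}


def test_rfe_degenerate_labels_rejected():
    rng = np.random.default_rng(0)
    X, _, _ = planted_table(rng, n=10, n_features=5)
    with pytest.raises(ValueError, match="class"):
        rfe_rank(X, np.zeros(10, dtype=int), 1)


def test_geometric_step_reaches_same_small_k_regime():
    rng = np.random.default_rng(7)
    X, y, planted = planted_table(rng, n=50, n_features=120, noise=0.2)
    res = rfe_rank(X, y, 1, step=0.2)
    assert res.survivors == planted
    assert len(res.elimination_order) == 119


# ---------------------------------------------- feature number by CV


def test_feature_number_deterministic_and_tabulated():
    rng = np.random.default_rng(5)
    X, y, _ = planted_table(rng, n=40, n_features=30, n_informative=3)
    cfg = SelectionConfig(seed=9)
    k1, t1 = determine_feature_number(X, y, cfg)
    k2, t2 = determine_feature_number(X, y, cfg)
    assert k1 == k2
    pd.testing.assert_frame_equal(t1, t2)
    assert t1.shape == (10, 5)
    assert ((t1 >= 0) & (t1 <= 1)).all().all()


def test_feature_number_tracks_planted_dimensionality():
    hits = 0
    n_rep = 8
    for seed in range(n_rep):
        rng = np.random.default_rng(100 + seed)
        X, y, _ = planted_table(
            rng, n=60, n_features=40, n_informative=3, noise=0.5
        )
        k, _ = determine_feature_number(X, y, SelectionConfig(seed=seed))
        hits += k in (2, 3, 4)
    assert hits >= 6


def test_pure_noise_has_no_consistently_winning_feature_number():
    wins = {}
    for seed in range(10):
        rng = np.random.default_rng(200 + seed)
        X, y, _ = planted_table(rng, n=40, n_features=30, n_informative=0)
        k, _ = determine_feature_number(X, y, SelectionConfig(seed=seed))
        wins[k] = wins.get(k, 0) + 1
    assert max(wins.values()) <= 5


# ------------------------------------------------- frequency voting


def test_frequencies_are_bounded_by_repeats():
    rng = np.random.default_rng(6)
    X, y, planted = planted_table(rng, noise=0.2)
    selected, freqs, _ = select_by_frequency(X, y, k=5, seed=3)
    assert len(selected) == 5
    assert ((freqs >= 1) & (freqs <= 5)).all()
    # a feature surviving every repeat is guaranteed in
    assert freqs[planted[0]] == 5
    assert planted[0] in selected


# ------------------------------------------------------------ pruning


def _exact_corr_table(corr, n=40, seed=0, seqs=None):
    """Columns with an exactly prescribed empirical correlation matrix."""
    rng = np.random.default_rng(seed)
    d = corr.shape[0]
    raw = rng.standard_normal((n, d + 2))
    raw -= raw.mean(axis=0)
    basis, _ = np.linalg.qr(raw)
    L = np.linalg.cholesky(corr)
    data = basis[:, :d] @ L.T
    seqs = seqs or ["GD"] * d
    cols = [_feature_name(i, s) for i, s in enumerate(seqs)]
    return pd.DataFrame(data, columns=cols)


def test_identical_columns_one_removed():
    X = _exact_corr_table(np.array([[1.0, 1.0 - 1e-12], [1.0 - 1e-12, 1.0]]))
    X.iloc[:, 1] = X.iloc[:, 0]
    kept = prune_correlated(list(X.columns), X)
    assert len(kept) == 1


def test_orthogonal_columns_untouched():
    X = _exact_corr_table(np.eye(4))
    kept = prune_correlated(list(X.columns), X)
    assert kept == list(X.columns)


def test_triple_prunes_lower_frequency_member():
    corr = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.2], [0.2, 0.2, 1.0]])
    X = _exact_corr_table(corr)
    a, b, c = X.columns
    freqs = pd.Series({a: 5.0, b: 2.0, c: 3.0})
    kept = prune_correlated([a, b, c], X, frequencies=freqs)
    assert kept == [a, c]


def test_pruning_is_per_sequence():
    # identical values but in different sequences: never compared, both kept
    X = _exact_corr_table(np.eye(2), seqs=["GD", "T2"])
    X.iloc[:, 1] = X.iloc[:, 0]
    kept = prune_correlated(list(X.columns), X)
    assert len(kept) == 2


def test_post_pruning_correlation_bound_holds():
    rng = np.random.default_rng(12)
    base = rng.standard_normal((30, 4))
    # correlated block: noisy copies of the same latent signal
    X = pd.DataFrame(
        np.column_stack([base[:, 0] + 0.1 * rng.standard_normal(30)
                         for _ in range(6)] + [base[:, 1], base[:, 2]]),
        columns=[_feature_name(i) for i in range(8)],
    )
    kept = prune_correlated(list(X.columns), X, threshold=0.7)
    if len(kept) > 1:
        corr = X[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.7


# ----------------------------------------------------- full selection


def test_run_selection_end_to_end_obeys_invariants():
    rng = np.random.default_rng(21)
    Xg, y, planted = planted_table(rng, n=40, n_features=20, noise=0.2)
    Xt, _, _ = planted_table(rng, n=40, n_features=20, seq="T2", n_informative=0)
    X = pd.concat([Xg, Xt], axis=1)
    result = run_selection(X, y, SelectionConfig(seed=2), k=3)
    assert result.chosen_k == 3
    assert planted[0] in result.pruned
    assert len(result.pruned) <= len(result.selected) <= 6  # 3 per sequence
    for seq in ("GD", "T2"):
        cols = [c for c in result.pruned if f"_{seq}_" in c]
        if len(cols) > 1:
            corr = X[cols].corr().abs().to_numpy()
            np.fill_diagonal(corr, 0)
            assert corr.max() <= 0.7 + 1e-12
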