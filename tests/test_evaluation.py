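"""Folds, oversampling, AUC and nested cross-validation."""

import itertools

import numpy as np
import pytest

from structimm.errors import ConfigError, MetricError
from structimm.evaluation import (eliminate_redundant_terms, nested_cv,
                                  oversample_minority, roc_auc,
                                  stratified_folds)


def _pools(n_self=60, n_imm=30, n_non=10):
    return np.array(["self"] * n_self + ["immunogenic"] * n_imm
                    + ["nonbinder"] * n_non)


def test_stratified_fold_sizes():
    pools = _pools(60, 30, 10)
    plan = stratified_folds(pools, k=5, seed=0)
    for fold in plan.folds:
        fp = pools[fold]
        assert np.sum(fp == "self") == 12
        assert np.sum(fp == "immunogenic") == 6
        assert np.sum(fp == "nonbinder") == 2


def test_folds_partition_everything():
    pools = _pools(57, 23, 11)
    plan = stratified_folds(pools, k=5, seed=1)
    allidx = np.concatenate(plan.folds)
    assert sorted(allidx) == list(range(len(pools)))
    for a, b in itertools.combinations(plan.folds, 2):
        assert not set(a) & set(b)
    sizes = [len(f) for f in plan.folds]
    assert max(sizes) - min(sizes) <= 3  # one per pool at most


def test_folds_deterministic():
    pools = _pools()
    p1 = stratified_folds(pools, k=5, seed=42)
    p2 = stratified_folds(pools, k=5, seed=42)
    for f1, f2 in zip(p1.folds, p2.folds):
        assert np.array_equal(f1, f2)


def test_small_pool_raises():
    pools = np.array(["self"] * 50 + ["immunogenic"] * 3)
    with pytest.raises(ConfigError):
        stratified_folds(pools, k=5)


def test_rotation_covers_all_roles():
    pools = _pools()
    plan = stratified_folds(pools, k=5, seed=0)
    test_folds = [tuple(plan.rotation(i)[2]) for i in range(5)]
    assert len(set(test_folds)) == 5  # every fold is the test set once
    train, val, test = plan.rotation(0)
    assert not set(train) & set(val)
    assert not set(train) & set(test)
    assert not set(val) & set(test)


def test_oversample_balances_classes():
    labels = np.array([0] * 90 + [1] * 10)
    idx = np.arange(100)
    aug = oversample_minority(idx, labels, seed=0)
    y_aug = labels[aug]
    assert np.sum(y_aug == 1) == np.sum(y_aug == 0) == 90
    # every added index is an existing positive
    added = aug[100:]
    assert np.all(labels[added] == 1)


def test_oversample_noop_when_balanced():
    labels = np.array([0] * 10 + [1] * 10)
    idx = np.arange(20)
    assert np.array_equal(oversample_minority(idx, labels, seed=0), idx)


def test_oversample_single_class_raises():
    with pytest.raises(MetricError):
        oversample_minority(np.arange(5), np.zeros(5), seed=0)


def test_auc_perfect_and_ties():
    assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0
    assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5


def test_auc_matches_exhaustive_pair_enumeration():
    scores = np.array([0.1, 0.4, 0.4, 0.8, 0.3, 0.7])
    labels = np.array([0, 1, 0, 1, 0, 1])
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    brute = np.mean([(1.0 if p > n else 0.5 if p == n else 0.0)
                     for p in pos for n in neg])
    assert roc_auc(scores, labels) == pytest.approx(brute, abs=1e-12)


def test_auc_complement_identity():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=40)  # tie-free with probability 1
    labels = (rng.uniform(size=40) < 0.4).astype(int)
    a = roc_auc(scores, labels)
    b = roc_auc(-scores, labels)
    assert a + b == pytest.approx(1.0, abs=1e-12)


def test_auc_cross_checked_against_sklearn():
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(17)
    scores = np.round(rng.uniform(size=60), 1)
    labels = (rng.uniform(size=60) < 0.35).astype(int)
    ours = roc_auc(scores, labels)
    theirs = sklearn_metrics.roc_auc_score(labels, scores)
    assert ours == pytest.approx(theirs, abs=1e-12)


def test_auc_single_class_raises():
    with pytest.raises(MetricError):
        roc_auc([0.1, 0.9], [1, 1])


def _planted_data(n=200, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.uniform(size=n) < 0.3).astype(int)
    pools = np.where(y == 1, "immunogenic", "self")
    x = rng.normal(size=(n, 3))
    x[:, 0] = y + 0.05 * rng.normal(size=n)  # near-perfect feature
    return x, y, pools


def test_nested_cv_recovers_planted_signal():
    x, y, pools = _planted_data()
    rep = nested_cv(x, y, pools, hidden_grid=(2,), seed=0, max_epochs=150)
    assert rep.cv_auc >= 0.98
    assert rep.total_auc >= 0.98
    assert rep.final_model is not None


def test_nested_cv_single_gridpoint_chosen():
    x, y, pools = _planted_data(n=100, seed=1)
    rep = nested_cv(x, y, pools, hidden_grid=(4,), seed=0, max_epochs=60,
                    refit=False)
    assert rep.chosen_hidden == 4
    assert rep.final_model is None


def test_nested_cv_null_band():
    """Labels independent of features: mean CV AUC near chance."""
    rng = np.random.default_rng(3)
    n = 500
    y = (rng.uniform(size=n) < 0.25).astype(int)
    pools = np.where(y == 1, "immunogenic", "self")
    x = rng.normal(size=(n, 5))
    aucs = []
    for s in range(3):
        rep = nested_cv(x, y, pools, hidden_grid=(3,), seed=s,
                        max_epochs=150, refit=False)
        aucs.append(rep.cv_auc)
    assert 0.45 <= np.mean(aucs) <= 0.55


def test_no_leakage_into_augmented_multiset():
    x, y, pools = _planted_data(n=100, seed=2)
    from structimm.evaluation import stratified_folds
    plan = stratified_folds(pools, k=5, seed=0)
    for i in range(5):
        train, val, test = plan.rotation(i)
        aug = oversample_minority(train, y, seed=i)
        assert not set(aug) & set(val)
        assert not set(aug) & set(test)


def test_duplicate_feature_column_eliminated():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(80, 3))
    x = np.column_stack([x, x[:, 0]])  # exact duplicate of column 0
    y = (x[:, 1] > 0).astype(int)
    pools = np.where(y == 1, "immunogenic", "self")
    names = ["a", "b", "c", "a_dup"]
    kept = eliminate_redundant_terms(x, names, y, pools, seed=0,
                                     auc_tolerance=None)
    assert ("a" in kept) != ("a_dup" in kept)  # exactly one survives
    assert "b" in kept and "c" in kept


def test_independent_features_survive_correlation_stage():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(120, 4))
    y = ((x.sum(axis=1) + 0.2 * rng.normal(size=120)) > 0).astype(int)
    pools = np.where(y == 1, "immunogenic", "self")
    kept = eliminate_redundant_terms(x, list("abcd"), y, pools, seed=0,
                                     auc_tolerance=None)
    assert kept == list("abcd")


def test_constant_feature_dropped_first():
    x = np.column_stack([np.ones(60), np.arange(60, dtype=float)])
    y = (x[:, 1] > 30).astype(int)
    pools = np.where(y == 1, "immunogenic", "self")
    kept = eliminate_redundant_terms(x, ["const", "signal"], y, pools,
                                     seed=0, auc_tolerance=None)
    assert kept == ["signal"]
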