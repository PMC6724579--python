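"""Nested cross-validation, oversampling, ROC/AUC and term selection.

The evaluation protocol mirrors the classic nested k-fold design: the data
are split into five pool-stratified sets; the sets rotate so each serves as
the held-out test while another is the validation set for early stopping
and the remaining three train the network.  Immunogenic (minority)
peptides are oversampled with replacement inside the training portion only
— validation and test folds are never resampled or used for
standardization, so no information leaks out of the training split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, MetricError
from .network import NetworkModel, NetworkSpec, forward, scg_train

DEFAULT_HIDDEN_GRID = (2, 3, 4, 6, 8, 10)


@dataclass
class FoldPlan:
    folds: list[np.ndarray]      # k disjoint index arrays covering the data
    seed: int = 0

    @property
    def k(self) -> int:
        return len(self.folds)

    def rotation(self, i: int):
        """(train, val, test) index arrays for rotation i."""
        k = self.k
        test = self.folds[i % k]
        val = self.folds[(i + 1) % k]
        train = np.concatenate([self.folds[(i + j) % k] for j in range(2, k)])
        return train, val, test


def stratified_folds(pools: np.ndarray, k: int = 5, seed: int = 0) -> FoldPlan:
    """Pool-stratified random partition into k folds, deterministic by seed."""
    pools = np.asarray(pools)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for pool in sorted(set(pools.tolist())):
        idx = np.where(pools == pool)[0]
        if len(idx) < k:
            raise ConfigError(f"pool {pool!r} has {len(idx)} members, "
                              f"fewer than k={k}")
        idx = rng.permutation(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(int(j))
    return FoldPlan(folds=[np.array(sorted(f), dtype=int) for f in folds],
                    seed=seed)


def oversample_minority(train_indices: np.ndarray, labels: np.ndarray,
                        seed: int = 0) -> np.ndarray:
    """Resample positive training examples with replacement to class balance.

    Returns an augmented index multiset (original indices plus resampled
    positives).  Only ever applied to training indices by contract.
    """
    train_indices = np.asarray(train_indices, dtype=int)
    y = np.asarray(labels)[train_indices]
    pos = train_indices[y == 1]
    neg = train_indices[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise MetricError("oversampling requires both classes in the training set")
    if len(pos) >= len(neg):
        return train_indices.copy()
    rng = np.random.default_rng(seed)
    extra = rng.choice(pos, size=len(neg) - len(pos), replace=True)
    return np.concatenate([train_indices, extra])


def roc_auc(scores, labels) -> float:
    """Rank-statistic AUC with ties counted 1/2.

    Exactly equals the probability that a random positive outscores a
    random negative (ties contributing one half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC undefined: both classes required")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores), dtype=float)
    sorted_scores = scores[order]
    i = 0
    rank = 1
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (rank + rank + (j - i))
        rank += j - i + 1
        i = j + 1
    r_pos = float(np.sum(ranks[labels == 1]))
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_curve_points(scores, labels) -> np.ndarray:
    """(fpr, tpr) points at every threshold, for TSV export / plotting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    n_pos, n_neg = max(tps[-1], 1), max(fps[-1], 1)
    pts = np.column_stack([fps / n_neg, tps / n_pos])
    return np.vstack([[0.0, 0.0], pts])


@dataclass
class SelectionReport:
    grid_auc: dict[int, float] = field(default_factory=dict)  # n_hidden -> mean AUC
    per_fold: dict[int, list[float]] = field(default_factory=dict)
    chosen_hidden: int = 0
    cv_auc: float = 0.0          # mean cross-validated AUC at the chosen point
    total_auc: float = 0.0       # AUC of the final all-data refit
    final_model: NetworkModel | None = None


def _train_eval_fold(x, y, train, val, test, n_hidden, seed, patience,
                     max_epochs):
    aug = oversample_minority(train, y, seed=seed)
    model = NetworkModel.initialize(NetworkSpec(x.shape[1], n_hidden), seed=seed)
    model = scg_train(model, x[aug], y[aug], x[val], y[val],
                      patience=patience, max_epochs=max_epochs)
    return roc_auc(forward(model, x[test]), y[test])


def nested_cv(x: np.ndarray, y: np.ndarray, pools: np.ndarray,
              hidden_grid=DEFAULT_HIDDEN_GRID, k: int = 5, seed: int = 0,
              patience: int = 6, max_epochs: int = 300,
              refit: bool = True) -> SelectionReport:
    """Grid search over hidden-layer sizes under rotated stratified folds.

    For every grid point each of the k rotations oversamples its training
    portion, trains with validation early stopping and scores the untouched
    test portion; the grid point with the best mean test AUC wins.  With
    *refit*, a final network of the chosen size is retrained on all data
    (with an internal validation split for stopping) and its AUC over the
    full dataset is reported separately, mirroring the cross-validated /
    total dual reporting convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    plan = stratified_folds(pools, k=k, seed=seed)
    report = SelectionReport()
    for n_hidden in hidden_grid:
        fold_aucs = []
        for i in range(k):
            train, val, test = plan.rotation(i)
            fold_aucs.append(_train_eval_fold(
                x, y, train, val, test, n_hidden,
                seed=seed + 1000 * n_hidden + i, patience=patience,
                max_epochs=max_epochs))
        report.per_fold[n_hidden] = fold_aucs
        report.grid_auc[n_hidden] = float(np.mean(fold_aucs))
    report.chosen_hidden = max(report.grid_auc, key=lambda h: report.grid_auc[h])
    report.cv_auc = report.grid_auc[report.chosen_hidden]
    if refit:
        train, val, _ = plan.rotation(0)
        all_idx = np.arange(len(y))
        aug = oversample_minority(np.concatenate([train, val]), y, seed=seed)
        model = NetworkModel.initialize(
            NetworkSpec(x.shape[1], report.chosen_hidden), seed=seed)
        model = scg_train(model, x[aug], y[aug], x[plan.folds[0]],
                          y[plan.folds[0]], patience=patience,
                          max_epochs=max_epochs)
        report.final_model = model
        report.total_auc = roc_auc(forward(model, x[all_idx]), y)
    return report


def eliminate_redundant_terms(x: np.ndarray, names: list[str], y: np.ndarray,
                              pools: np.ndarray, seed: int = 0,
                              corr_threshold: float = 0.95,
                              auc_tolerance: float | None = 0.002,
                              n_hidden: int = 5, k: int = 5,
                              max_epochs: int = 150) -> list[str]:
    """Two-stage redundancy elimination; returns the surviving term names.

    Stage 1 drops constant columns, then one member of every feature pair
    whose absolute Pearson correlation exceeds *corr_threshold* (the
    earlier column survives).  Stage 2 (skipped when *auc_tolerance* is
    None) backward-eliminates features whose removal does not reduce the
    mean cross-validated AUC by more than the tolerance.
    """
    x = np.asarray(x, dtype=float)
    keep = [i for i in range(x.shape[1]) if np.std(x[:, i]) > 0]
    # correlation stage
    surviving = []
    for i in keep:
        redundant = False
        for j in surviving:
            c = np.corrcoef(x[:, i], x[:, j])[0, 1]
            if abs(c) > corr_threshold:
                redundant = True
                break
        if not redundant:
            surviving.append(i)
    if auc_tolerance is not None and len(surviving) > 1:
        def cv_auc(cols):
            rep = nested_cv(x[:, cols], y, pools, hidden_grid=(n_hidden,),
                            k=k, seed=seed, max_epochs=max_epochs, refit=False)
            return rep.cv_auc
        base = cv_auc(surviving)
        improved = True
        while improved and len(surviving) > 1:
            improved = False
            for i in list(surviving):
                trial = [j for j in surviving if j != i]
                a = cv_auc(trial)
                if a >= base - auc_tolerance:
                    surviving = trial
                    base = max(base, a)
                    improved = True
                    break
    return [names[i] for i in surviving]
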