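"""SVM evaluation harness for precomputed kernels.

The protocol is two-times-nested stratified cross-validation: an inner
CV loop on each outer-training portion selects the kernel hyperparameters
and SVM regularization C, and the outer loop estimates prediction
performance with the selected configuration. Gram matrices are computed
once over all examples and only ever *subset* per fold — never recomputed —
so model selection sees exactly the kernel the final model uses.

Ranking quality is measured by auROC (Mann–Whitney: probability that a
random positive outranks a random negative, ties counted half) and by
ROC50, the area under the ROC curve up to the 50th false positive,
normalized so a perfect ranking scores 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "auroc",
    "roc50",
    "CVPlan",
    "EvalResult",
    "nested_cv",
    "learning_curve",
    "paired_comparison",
    "ComparisonResult",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes present to compute a ranking score")
    return labels


def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann–Whitney formulation, ties half)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels == np.max(labels), np.asarray(scores, dtype=float)))


def roc50(scores, labels, cutoff: int = 50) -> float:
    """Area under the ROC curve up to the ``cutoff``-th false positive.

    Equals the Mann–Whitney auROC computed between all positives and the
    ``cutoff`` highest-scoring negatives (negatives tied at the boundary
    are interchangeable), which is the truncated-curve area normalized so
    a perfect ranking scores 1. With fewer than ``cutoff`` negatives this
    is the plain auROC.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    pos_mask = labels == np.max(labels)
    neg_idx = np.nonzero(~pos_mask)[0]
    if len(neg_idx) > cutoff:
        top = neg_idx[np.argsort(-scores[neg_idx], kind="stable")[:cutoff]]
        keep = np.concatenate([np.nonzero(pos_mask)[0], top])
        scores, labels = scores[keep], labels[keep]
    return auroc(scores, labels)


@dataclass(frozen=True)
class CVPlan:
    """Nested-CV configuration; folds are label-stratified."""

    outer_folds: int = 5
    inner_folds: int = 5
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.C_grid:
            raise ValueError("C grid must be non-empty")


@dataclass
class EvalResult:
    fold_scores: list[float]
    selected: list[tuple[str, float]]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_scores))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_scores))


def _fit_score(K: np.ndarray, y: np.ndarray, train, test, C: float) -> float:
    svc = SVC(C=C, kernel="precomputed")
    svc.fit(K[np.ix_(train, train)], y[train])
    return auroc(svc.decision_function(K[np.ix_(test, train)]), y[test])


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int):
    _, counts = np.unique(np.asarray(y), return_counts=True)
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("stratification needs at least two examples of each class")
    folds = min(n_folds, int(counts.min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _select(grams: dict[str, np.ndarray], y, train_idx, plan: CVPlan) -> tuple[str, float]:
    """Inner-CV model selection on the training portion only.

    The grid is iterated in documented order (Gram keys in insertion order,
    then C ascending as given); ties keep the first grid point.
    """
    train_idx = np.asarray(train_idx)
    y_tr = y[train_idx]
    inner = _stratified_folds(y_tr, plan.inner_folds, plan.seed + 1)
    best = None
    for key, K in grams.items():
        K_tr = K[np.ix_(train_idx, train_idx)]
        for C in plan.C_grid:
            scores = [_fit_score(K_tr, y_tr, tr, te, C) for tr, te in inner]
            mean = float(np.mean(scores))
            if best is None or mean > best[0] + 1e-12:
                best = (mean, key, C)
    return best[1], best[2]


def nested_cv(grams: dict[str, np.ndarray], labels, plan: CVPlan | None = None) -> EvalResult:
    """Two-times-nested stratified CV over a family of precomputed kernels.

    ``grams`` maps hyperparameter names to full n×n Gram matrices; the grid
    is their keys crossed with the C grid. Per outer fold the inner loop
    selects a grid point, an SVM is refit on the whole outer-training
    portion at that point, and the outer-test auROC is recorded.
    """
    plan = plan or CVPlan()
    y = np.asarray(labels)
    outer = _stratified_folds(y, plan.outer_folds, plan.seed)
    fold_scores, selected = [], []
    for train, test in outer:
        key, C = _select(grams, y, train, plan)
        fold_scores.append(_fit_score(grams[key], y, train, test, C))
        selected.append((key, C))
    return EvalResult(fold_scores=fold_scores, selected=selected)


def _stratified_subsample(rng: np.random.Generator, idx: np.ndarray, y: np.ndarray, size: int):
    """Subsample ``size`` indices from ``idx`` keeping class proportions."""
    classes = np.unique(y[idx])
    parts = []
    remaining = size
    for i, c in enumerate(classes):
        pool = idx[y[idx] == c]
        take = round(size * len(pool) / len(idx)) if i < len(classes) - 1 else remaining
        take = min(max(take, 1), len(pool), remaining)
        parts.append(rng.choice(pool, size=take, replace=False))
        remaining -= take
    return np.concatenate(parts)


def learning_curve(
    grams: dict[str, dict[str, np.ndarray]],
    labels,
    sizes=(20, 31, 50, 80, 128, 204, 324, 516, 822, 1308),
    repeats: int = 10,
    seed: int = 0,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    inner_folds: int = 5,
    test_fraction: float = 0.3,
) -> dict[str, dict[int, dict]]:
    """Test auROC versus training-set size for one or more kernel families.

    Per repeat, ``test_fraction`` of the data is held out, each training
    size is subsampled (stratified) from the rest, hyperparameters are
    selected by inner CV on the subsample, and the refit model is scored
    on the held-out test set. ``grams[kernel][grid_point]`` are full-data
    Gram matrices. Returns per kernel and size the mean/std/values.
    """
    y = np.asarray(labels)
    n = len(y)
    max_train = n - int(round(n * test_fraction))
    sizes = [int(s) for s in sizes]
    for s in sizes:
        if s > max_train:
            raise ValueError(f"training size {s} exceeds available {max_train} examples")
    results: dict[str, dict[int, list[float]]] = {k: {s: [] for s in sizes} for k in grams}
    for rep in range(repeats):
        rng = np.random.default_rng(seed + rep)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        perm = rng.permutation(n)
        n_test = int(round(n * test_fraction))
        test_idx, pool = perm[:n_test], perm[n_test:]
        if len(np.unique(y[test_idx])) < 2:
            continue
        for size in sizes:
            train_idx = _stratified_subsample(rng, pool, y, size)
            plan = CVPlan(inner_folds=inner_folds, C_grid=C_grid, seed=rep_seed)
            for kernel, family in grams.items():
                key, C = _select(family, y, train_idx, plan)
                score = _fit_score(family[key], y, train_idx, test_idx, C)
                results[kernel][size].append(score)
    return {
        k: {
            s: {"mean": float(np.mean(v)), "std": float(np.std(v)), "scores": v}
            for s, v in per_size.items()
        }
        for k, per_size in results.items()
    }


@dataclass
class ComparisonResult:
    wins: int
    ties: int
    losses: int
    p_value: float


def paired_comparison(results_a, results_b, tol: float = 1e-6) -> ComparisonResult:
    """Win/tie/loss counts for A vs B over tasks, with a one-sided sign test.

    Ties (|a − b| ≤ tol) are excluded from the binomial test; with no
    non-tied tasks the p-value is 1 (nothing to detect).
    """
    a = np.asarray(results_a, dtype=float)
    b = np.asarray(results_b, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("need two equal-length, non-empty result lists")
    diff = a - b
    wins = int((diff > tol).sum())
    losses = int((diff < -tol).sum())
    ties = int(a.size - wins - losses)
    n = wins + losses
    p = 1.0 if n == 0 else float(binomtest(wins, n, 0.5, alternative="greater").pvalue)
    return ComparisonResult(wins=wins, ties=ties, losses=losses, p_value=p)
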