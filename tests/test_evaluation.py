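import math

import numpy as np
import pytest

from aakernels import (
    CVPlan,
    SubstringKernelSpec,
    SyntheticSpec,
    WDKernel,
    WDParams,
    auroc,
    generate_binding_dataset,
    get_encoding,
    gram_matrix,
    learning_curve,
    nested_cv,
    paired_comparison,
    roc50,
)


def brute_force_auroc(scores, labels):
    """All-pairs Mann–Whitney: P(random positive outranks random negative)."""
    scores = np.asarray(scores)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == -1]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def walk_roc50(scores, labels, cutoff=50):
    """Literal oracle: walk the ranking, accumulate the truncated ROC area,
    stop after `cutoff` false positives (continuous scores assumed)."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order]
    n_pos = int((y == 1).sum())
    n_neg_total = int((y == -1).sum())
    denom = n_pos * min(cutoff, n_neg_total)
    tp = fp = 0
    area = 0.0
    for lab in y:
        if lab == 1:
            tp += 1
        else:
            fp += 1
            area += tp  # horizontal step at the current TP height
            if fp == cutoff:
                break
    return area / denom


class TestAuroc:
    def test_perfect_and_reversed(self):
        labels = [1, 1, -1, -1]
        assert auroc([4, 3, 2, 1], labels) == 1.0
        assert auroc([1, 2, 3, 4], labels) == 0.0

    def test_half_ordered_example(self):
        assert auroc([0.9, 0.8, 0.7], [1, -1, 1]) == 0.5

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            labels = rng.choice([-1, 1], size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = rng.choice(np.linspace(0, 1, 17), size=n)  # forces ties
            assert auroc(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc([1, 2, 3], [1, 1, 1])


class TestRoc50:
    def test_perfect_and_worst(self):
        labels = [1] * 5 + [-1] * 100
        assert roc50(np.arange(105)[::-1], labels) == 1.0
        assert roc50(np.arange(105), labels) == 0.0

    def test_equals_auroc_when_few_negatives(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            labels = np.array([1] * 30 + [-1] * 40)
            scores = rng.normal(size=len(labels))
            assert roc50(scores, labels) == auroc(scores, labels)
            assert roc50(scores, labels, cutoff=40) == auroc(scores, labels)

    def test_matches_literal_walk_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n_pos, n_neg = int(rng.integers(5, 40)), int(rng.integers(60, 200))
            labels = np.array([1] * n_pos + [-1] * n_neg)
            scores = rng.normal(size=len(labels))  # continuous: no ties
            assert roc50(scores, labels) == pytest.approx(
                walk_roc50(scores, labels), abs=1e-12
            )


@pytest.fixture(scope="module")
def planted():
    enc = get_encoding("zscale")
    ds = generate_binding_dataset(SyntheticSpec(n=120, effect=1.0, seed=20), enc)
    spec = SubstringKernelSpec("rbf", encoding=enc, sigma=1.0)
    grams = {
        "wd": gram_matrix(ds.sequences, WDKernel(WDParams(max_degree=3))).values,
        "wd-rbf": gram_matrix(
            ds.sequences, WDKernel(WDParams(max_degree=3, substring_spec=spec))
        ).values,
    }
    return ds, grams


class TestNestedCV:
    def test_separable_data_scores_high(self, planted):
        ds, grams = planted
        res = nested_cv(grams, ds.labels, CVPlan(seed=1, C_grid=(0.1, 1.0, 10.0)))
        assert res.mean > 0.9
        assert len(res.fold_scores) == 5

    def test_null_data_scores_near_chance(self):
        ds = generate_binding_dataset(SyntheticSpec(n=150, effect=0.0, seed=21))
        K = gram_matrix(ds.sequences, WDKernel(WDParams(max_degree=3))).values
        res = nested_cv({"wd": K}, ds.labels, CVPlan(seed=2, C_grid=(1.0,)))
        assert 0.35 <= res.mean <= 0.65

    def test_single_grid_point_reduces_to_plain_cv(self, planted):
        """With one grid point, selection is forced and nested CV is plain
        outer CV at that configuration."""
        ds, grams = planted
        plan = CVPlan(seed=3, C_grid=(1.0,))
        res = nested_cv({"wd": grams["wd"]}, ds.labels, plan)
        from aakernels.evaluation import _fit_score, _stratified_folds

        y = ds.labels
        manual = [
            _fit_score(grams["wd"], y, tr, te, 1.0)
            for tr, te in _stratified_folds(y, 5, plan.seed)
        ]
        assert res.fold_scores == pytest.approx(manual, abs=0)
        assert all(sel == ("wd", 1.0) for sel in res.selected)

    def test_no_leakage_from_outer_test_labels(self, planted):
        """Permuting outer-test labels must not change selected hyperparameters."""
        from aakernels.evaluation import _select, _stratified_folds

        ds, grams = planted
        plan = CVPlan(seed=4, C_grid=(0.1, 1.0, 10.0))
        y = ds.labels.copy()
        rng = np.random.default_rng(5)
        for train, test in _stratified_folds(y, 5, plan.seed):
            sel_before = _select(grams, y, train, plan)
            y_perm = y.copy()
            y_perm[test] = rng.permutation(y_perm[test])
            sel_after = _select(grams, y_perm, train, plan)
            assert sel_before == sel_after

    def test_fold_assignment_pure_function_of_seed(self, planted):
        ds, grams = planted
        plan = CVPlan(seed=6, C_grid=(1.0,))
        r1 = nested_cv(grams, ds.labels, plan)
        r2 = nested_cv(grams, ds.labels, plan)
        assert r1.fold_scores == r2.fold_scores
        assert r1.selected == r2.selected

    def test_single_class_rejected(self, planted):
        _, grams = planted
        with pytest.raises(ValueError, match="each class"):
            nested_cv(grams, np.ones(120, dtype=int), CVPlan())


class TestLearningCurve:
    def test_default_size_ladder(self):
        import inspect

        sig = inspect.signature(learning_curve)
        assert sig.parameters["sizes"].default == (
            20, 31, 50, 80, 128, 204, 324, 516, 822, 1308)

    def test_size_exceeding_training_pool_rejected(self, planted):
        ds, grams = planted
        with pytest.raises(ValueError, match="exceeds"):
            learning_curve({"wd": {"wd": grams["wd"]}}, ds.labels, sizes=[2000], repeats=1)

    def test_reproducible_and_improves_with_size(self, planted):
        ds, grams = planted
        kw = dict(sizes=[20, 60], repeats=3, seed=7, C_grid=(1.0,), inner_folds=3)
        r1 = learning_curve({"wd": {"wd": grams["wd"]}}, ds.labels, **kw)
        r2 = learning_curve({"wd": {"wd": grams["wd"]}}, ds.labels, **kw)
        assert r1["wd"][20]["scores"] == r2["wd"][20]["scores"]
        # planted signal: more data should not hurt (up to generous noise)
        assert r1["wd"][60]["mean"] >= r1["wd"][20]["mean"] - 0.1


class TestPairedComparison:
    def test_identical_lists_all_ties(self):
        res = paired_comparison([0.9, 0.8], [0.9, 0.8])
        assert (res.wins, res.ties, res.losses) == (0, 2, 0)
        assert res.p_value == 1.0

    def test_all_wins_closed_form(self):
        res = paired_comparison([1.0] * 10, [0.0] * 10)
        assert res.p_value == pytest.approx(2.0**-10)

    def test_eight_wins_two_losses(self):
        a = [1.0] * 8 + [0.0] * 2
        b = [0.0] * 8 + [1.0] * 2
        res = paired_comparison(a, b)
        assert (res.wins, res.losses) == (8, 2)
        assert res.p_value == pytest.approx(56 / 1024)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            paired_comparison([], [])
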