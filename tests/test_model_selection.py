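"""Nested CV: fold plans, grid selection, metrics, leakage and determinism."""

import numpy as np
import pandas as pd
import pytest

from adps.linear_model import RegularizationPair, lambda_max
from adps.model_selection import (
    SearchGrid,
    inner_select,
    make_fold_plan,
    nested_cv_evaluate,
    performance_metrics,
    select_and_fit_full,
)


@pytest.fixture(scope="module")
def separated_clouds():
    """Two Gaussian clouds 10 SD apart: Bayes error effectively zero."""
    rng = np.random.default_rng(2)
    n, p = 60, 20
    y = np.r_[np.zeros(30), np.ones(30)]
    X = rng.normal(size=(n, p))
    X[y == 1, :5] += 10.0
    return X, y


class TestFoldPlan:
    def test_balanced_20_subjects_k1_10(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        plan = make_fold_plan(y, 10, 5, seed=1)
        for k in range(10):
            fold_labels = sorted(y[plan.test_subjects(k)].tolist())
            assert fold_labels == [0.0, 1.0]  # forced by stratification

    def test_stratification_within_one_subject(self):
        rng = np.random.default_rng(0)
        y = (rng.random(73) < 0.4).astype(float)
        plan = make_fold_plan(y, 5, 5, seed=3)
        overall = y.mean()
        for k in range(5):
            fold = y[plan.test_subjects(k)]
            expected_pos = overall * len(fold)
            assert abs(fold.sum() - expected_pos) <= 1.0

    def test_internal_never_includes_heldout(self):
        y = np.r_[np.zeros(20), np.ones(20)]
        plan = make_fold_plan(y, 5, 3, seed=2)
        for k in range(5):
            held = plan.test_subjects(k)
            assert np.all(plan.internal[k][held] == -1)
            retained = plan.training_subjects(k)
            assert np.all(plan.internal[k][retained] >= 0)

    def test_same_seed_identical_plan(self):
        y = np.r_[np.zeros(15), np.ones(15)]
        p1 = make_fold_plan(y, 5, 3, seed=9)
        p2 = make_fold_plan(y, 5, 3, seed=9)
        assert np.array_equal(p1.external, p2.external)
        assert all(np.array_equal(a, b) for a, b in zip(p1.internal, p2.internal))

    def test_different_seeds_differ(self):
        y = np.r_[np.zeros(50), np.ones(50)]
        p1 = make_fold_plan(y, 5, 3, seed=1)
        p2 = make_fold_plan(y, 5, 3, seed=2)
        assert not np.array_equal(p1.external, p2.external)

    def test_class_too_small_rejected(self):
        y = np.r_[np.zeros(3), np.ones(20)]
        with pytest.raises(ValueError):
            make_fold_plan(y, 5, 3, seed=0)


class TestPerformanceMetrics:
    @pytest.mark.parametrize(
        "truth,pred,expected",
        [
            ([1, 1, 0, 0], [1, 0, 0, 0], (75.0, 50.0, 100.0)),
            ([1, 0, 1, 0], [1, 0, 1, 0], (100.0, 100.0, 100.0)),
            ([1, 0, 1, 0], [0, 1, 0, 1], (0.0, 0.0, 0.0)),
        ],
    )
    def test_counts(self, truth, pred, expected):
        m = performance_metrics(truth, pred)
        assert (m["accuracy"], m["sensitivity"], m["specificity"]) == expected

    def test_empty_class_is_missing_not_zero(self):
        m = performance_metrics([0, 0], [0, 1])
        assert np.isnan(m["sensitivity"])
        assert m["specificity"] == 50.0


class TestInnerSelect:
    def test_single_grid_point_returned(self, separated_clouds):
        X, y = separated_clouds
        fold_ids = make_fold_plan(y, 2, 3, seed=0).internal[0]
        fold_ids = fold_ids[fold_ids >= 0]
        Xr = X[make_fold_plan(y, 2, 3, seed=0).training_subjects(0)]
        yr = y[make_fold_plan(y, 2, 3, seed=0).training_subjects(0)]
        grid = SearchGrid(alpha_values=(0.5,), lambda_values=(0.2,))
        sel = inner_select(Xr, yr, fold_ids, grid)
        assert sel.pair == RegularizationPair(0.5, 0.2)

    def test_exact_ties_break_to_largest_lam_then_alpha(self):
        """All-zero models at every grid point predict identically, so the
        stated tie rule must pick the largest lam, then the largest alpha."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 5))
        y = np.r_[np.zeros(20), np.ones(20)]
        lmax = max(lambda_max(X, y, a) for a in (0.5, 1.0))
        grid = SearchGrid(alpha_values=(0.5, 1.0),
                          lambda_values=(4 * lmax, 3 * lmax, 2 * lmax))
        fold_ids = np.tile([0, 1, 2, 3], 10)
        sel = inner_select(X, y, fold_ids, grid)
        assert sel.pair.lam == pytest.approx(4 * lmax)
        assert sel.pair.alpha == 1.0

    def test_strongly_better_lambda_always_selected(self, separated_clouds):
        """With an empty-model penalty against a moderate one, the signal is
        recoverable only at the moderate penalty, which must win every time."""
        X, y = separated_clouds
        lmax = lambda_max(X, y, 0.5)
        grid = SearchGrid(alpha_values=(0.5,), lambda_values=(2 * lmax, 0.2 * lmax))
        for seed in range(10):
            plan = make_fold_plan(y, 2, 5, seed=seed)
            tr = plan.training_subjects(0)
            sel = inner_select(X[tr], y[tr], plan.internal[0][tr], grid)
            assert sel.pair.lam == pytest.approx(0.2 * lmax)

    def test_average_rule_returns_interior_pair(self, separated_clouds):
        X, y = separated_clouds
        plan = make_fold_plan(y, 2, 5, seed=1)
        tr = plan.training_subjects(0)
        grid = SearchGrid(alpha_values=(0.5,))
        sel = inner_select(X[tr], y[tr], plan.internal[0][tr], grid,
                           selection_rule="average")
        paths = sel.lambda_paths[0]
        assert paths.min() <= sel.pair.lam <= paths.max()
        assert sel.pair.alpha == 0.5


class TestNestedCV:
    def test_separated_clouds_median_accuracy_100(self, separated_clouds):
        X, y = separated_clouds
        perf = nested_cv_evaluate(X, y, SearchGrid(), K1=5, K2=5,
                                  repetitions=3, base_seed=7)
        assert perf.median_accuracy == 100.0
        assert perf.audit_leakage()

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 10))
        y = np.r_[np.zeros(30), np.ones(30)]
        rng.shuffle(y)
        perf = nested_cv_evaluate(X, y, SearchGrid(), K1=5, K2=5,
                                  repetitions=5, base_seed=13)
        assert 35.0 <= perf.median_accuracy <= 65.0

    def test_repetition_results_independent_of_total(self, separated_clouds):
        X, y = separated_clouds
        one = nested_cv_evaluate(X, y, SearchGrid(), K1=5, K2=5,
                                 repetitions=1, base_seed=7)
        three = nested_cv_evaluate(X, y, SearchGrid(), K1=5, K2=5,
                                   repetitions=3, base_seed=7)
        np.testing.assert_array_equal(one.oof_probabilities[:, 0],
                                      three.oof_probabilities[:, 0])
        pd.testing.assert_frame_equal(one.fold_records,
                                      three.fold_records.iloc[: len(one.fold_records)])

    def test_median_is_empirical_median(self, separated_clouds):
        X, y = separated_clouds
        perf = nested_cv_evaluate(X, y, SearchGrid(), K1=5, K2=5,
                                  repetitions=3, base_seed=11)
        assert perf.median_accuracy == float(np.median(perf.per_repetition["accuracy"]))

    def test_every_subject_scored_once_per_repetition(self, separated_clouds):
        X, y = separated_clouds
        perf = nested_cv_evaluate(X, y, SearchGrid(), K1=5, K2=5,
                                  repetitions=2, base_seed=3)
        assert not np.any(np.isnan(perf.oof_probabilities))
        assert perf.oof_probabilities.shape == (len(y), 2)


class TestSelectAndFitFull:
    def test_deterministic_and_uses_all_data(self, separated_clouds):
        X, y = separated_clouds
        pair1, model1 = select_and_fit_full(X, y, SearchGrid(), K2=5, seed=4)
        pair2, model2 = select_and_fit_full(X, y, SearchGrid(), K2=5, seed=4)
        assert pair1 == pair2
        np.testing.assert_array_equal(model1.coefficients, model2.coefficients)
        assert model1.converged
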