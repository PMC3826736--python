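"""Nested (three-way-split) cross-validation with grid search.

The protocol: an external K1-fold CV holds one fold out for testing; the
remaining K1-1 folds are split again into K2 internal folds, and a grid
search over the regularization parameters picks the pair maximizing mean
validation accuracy across the K2 folds. The classifier is then refitted on
all K1-1 folds at the selected pair and evaluated on the held-out fold. The
whole procedure is repeated with fresh random partitions and the median
accuracy/sensitivity/specificity across repetitions is reported — this is
what keeps the performance estimates, and the out-of-fold scores derived
from them, free of selection optimism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .linear_model import (
    ConvergenceError,
    RegularizationPair,
    _validate_labels,
    _values,
    enet_logistic_path,
    fit_elastic_net_logistic,
    lambda_max,
)

__all__ = [
    "FoldPlan",
    "SearchGrid",
    "CVPerformance",
    "make_fold_plan",
    "inner_select",
    "nested_cv_evaluate",
    "performance_metrics",
    "select_and_fit_full",
]


def _rep_seed_sequence(base_seed: int, rep: int) -> np.random.SeedSequence:
    """Seed stream for one repetition, independent of the repetition count."""
    return np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(rep),))


def _kfold_assignment(labels, k, random_state) -> np.ndarray:
    """Stratified fold ids (0..k-1) for every subject."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=random_state)
    out = np.full(len(labels), -1, dtype=int)
    for fold, (_, test) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        out[test] = fold
    return out


# ---------------------------------------------------------------------------
# fold plan


@dataclass(frozen=True)
class FoldPlan:
    """Class-stratified external/internal fold assignments for one repetition.

    ``external[i]`` is subject i's external fold in 0..K1-1. ``internal[k]``
    assigns each subject retained when fold k is held out to an internal fold
    in 0..K2-1 (held-out subjects carry -1).
    """

    n_subjects: int
    K1: int
    K2: int
    seed: int
    external: np.ndarray
    internal: tuple

    def training_subjects(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.external != fold)

    def test_subjects(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.external == fold)


def make_fold_plan(labels, K1: int, K2: int, seed: int) -> FoldPlan:
    """Build a stratified nested fold plan; identical seed => identical plan."""
    y = _validate_labels(labels)
    n = len(y)
    if K1 < 2 or K2 < 2:
        raise ValueError("K1 and K2 must both be >= 2")
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < K1:
        raise ValueError(
            f"smallest class has {counts.min()} members; needs >= K1={K1} for stratification"
        )
    retained_min = counts.min() - int(np.ceil(counts.min() / K1))
    if retained_min < K2:
        raise ValueError("smallest class too small for the internal K2-fold split")
    ss = np.random.SeedSequence(entropy=int(seed))
    states = ss.generate_state(K1 + 1)
    external = _kfold_assignment(y, K1, int(states[0]))
    internal = []
    for k in range(K1):
        ids = np.flatnonzero(external != k)
        assign = np.full(n, -1, dtype=int)
        assign[ids] = _kfold_assignment(y[ids], K2, int(states[k + 1]))
        internal.append(assign)
    return FoldPlan(n, K1, K2, int(seed), external, tuple(internal))


# ---------------------------------------------------------------------------
# search grid


@dataclass(frozen=True)
class SearchGrid:
    """Regularization grid: alphas x a decreasing lambda path.

    If ``lambda_values`` is None the path is rebuilt on each training subset
    as ``n_lambda`` log-spaced points from lambda_max down to
    ``lambda_min_ratio * lambda_max``, keeping the path anchored to the fold
    composition. When ``lambda_min_ratio`` is left as None it follows the
    coordinate-descent solver family's convention: 1e-4 when there are more
    subjects than variables, 0.01 in the p >= n regime (where the bottom of
    the 1e-4 path is an effectively unpenalized, non-identifiable fit).
    Voxel data conventionally fixes a single alpha; the default 0.1 keeps a
    strong quadratic (grouping) share so that spatially clustered, mutually
    correlated voxels enter the model together rather than being pruned to
    one representative — the property that makes the discriminative maps
    stable across repetitions. Cognitive data searches a 2-D grid.
    """

    alpha_values: tuple = (0.1,)
    lambda_values: Optional[tuple] = None
    n_lambda: int = 20
    lambda_min_ratio: Optional[float] = None

    def __post_init__(self):
        alphas = tuple(float(a) for a in self.alpha_values)
        if not alphas:
            raise ValueError("alpha_values must be non-empty")
        if any(a <= 0 or a > 1 for a in alphas):
            raise ValueError("grid alphas must lie in (0, 1]")
        object.__setattr__(self, "alpha_values", alphas)
        if self.lambda_values is not None:
            lams = tuple(float(l) for l in self.lambda_values)
            if not lams or any(np.diff(lams) >= 0):
                raise ValueError("lambda_values must be a non-empty strictly decreasing list")
            object.__setattr__(self, "lambda_values", lams)

    @classmethod
    def for_modality(cls, variable_kind: str, fixed_alpha: float = 0.1,
                     n_lambda: int = 20, lambda_min_ratio: Optional[float] = None) -> "SearchGrid":
        if variable_kind == "cognitive":
            alphas = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
        else:
            alphas = (fixed_alpha,)
        return cls(alphas, None, n_lambda, lambda_min_ratio)

    def materialize(self, X, y) -> list:
        """Per-alpha decreasing lambda arrays for the given training data."""
        Xv = _values(X)
        ratio = self.lambda_min_ratio
        if ratio is None:
            n, p = Xv.shape
            ratio = 1e-4 if n > p else 1e-2
        out = []
        for a in self.alpha_values:
            if self.lambda_values is not None:
                out.append(np.asarray(self.lambda_values, dtype=float))
            else:
                lmax = lambda_max(Xv, y, a)
                out.append(np.geomspace(lmax, lmax * ratio, self.n_lambda))
        return out


@dataclass(frozen=True)
class SelectionResult:
    pair: RegularizationPair
    mean_accuracy: np.ndarray      # (n_alpha, n_lambda) validation accuracies
    lambda_paths: tuple            # per-alpha lambda arrays


def inner_select(
    X,
    y,
    fold_ids,
    grid: SearchGrid,
    tol: float = 1e-7,
    selection_rule: str = "best",
) -> SelectionResult:
    """Grid search over the K2 internal folds of one external training set.

    ``fold_ids`` assigns every training subject to an internal fold. Returns
    the pair maximizing mean validation accuracy; exact ties break toward
    larger lambda, then larger alpha (the sparser model).

    ``selection_rule="average"`` instead records the best pair per internal
    fold and averages the selected lambdas and alphas across folds — the
    variant described alongside the main selection rule in the source
    protocol's supplementary illustration.
    """
    if selection_rule not in ("best", "average"):
        raise ValueError("selection_rule must be 'best' or 'average'")
    Xv = _values(X)
    y = _validate_labels(y)
    fold_ids = np.asarray(fold_ids)
    K2 = int(fold_ids.max()) + 1
    paths = grid.materialize(Xv, y)
    n_alpha = len(grid.alpha_values)
    n_lam = max(len(p) for p in paths)
    acc_f = np.zeros((K2, n_alpha, n_lam))
    for k in range(K2):
        tr = fold_ids != k
        va = ~tr
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError("degenerate internal fold (single class)")
        for ai, alpha in enumerate(grid.alpha_values):
            lams = paths[ai]
            b0s, coefs = enet_logistic_path(Xv[tr], y[tr], alpha, lams, tol=tol)
            prob = expit(b0s[None, :] + Xv[va] @ coefs)
            pred = prob > 0.5
            acc_f[k, ai, : len(lams)] = (pred == y[va, None]).mean(axis=0)
    acc = acc_f.mean(axis=0)

    def _best_pair(a):
        best = a.max()
        ties = np.argwhere(a >= best - 1e-12)
        # prefer larger lam, then larger alpha (the sparser model)
        cand = sorted(
            (float(paths[ai][li]), float(grid.alpha_values[ai]))
            for ai, li in ties
        )
        lam, alpha = cand[-1]
        return RegularizationPair(alpha=alpha, lam=lam)

    if selection_rule == "best":
        pair = _best_pair(acc)
    else:
        per_fold = [_best_pair(acc_f[k]) for k in range(K2)]
        pair = RegularizationPair(
            alpha=float(np.mean([p.alpha for p in per_fold])),
            lam=float(np.mean([p.lam for p in per_fold])),
        )
    return SelectionResult(pair, acc, tuple(paths))


# ---------------------------------------------------------------------------
# performance metrics


def performance_metrics(y_true, y_pred) -> dict:
    """Accuracy, sensitivity (TPR on class 1), specificity (TNR on class 0), in percent.

    An empty class yields NaN for the undefined metric rather than zero.
    """
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    acc = 100.0 * float(np.mean(y_true == y_pred))
    pos = y_true == 1
    neg = ~pos
    sens = 100.0 * float(np.mean(y_pred[pos] == 1)) if pos.any() else float("nan")
    spec = 100.0 * float(np.mean(y_pred[neg] == 0)) if neg.any() else float("nan")
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec}


# ---------------------------------------------------------------------------
# nested CV


@dataclass
class CVPerformance:
    """Nested-CV output: per-repetition metrics, medians, out-of-fold scores."""

    per_repetition: pd.DataFrame       # repetition, accuracy, sensitivity, specificity
    fold_records: pd.DataFrame         # repetition, fold, alpha, lam, metrics
    oof_probabilities: np.ndarray      # (n_subjects, repetitions)
    external_assignments: np.ndarray   # (n_subjects, repetitions) fold ids (provenance)
    K1: int
    K2: int
    base_seed: int

    @property
    def median_accuracy(self) -> float:
        return float(self.per_repetition["accuracy"].median())

    @property
    def median_sensitivity(self) -> float:
        return float(self.per_repetition["sensitivity"].median())

    @property
    def median_specificity(self) -> float:
        return float(self.per_repetition["specificity"].median())

    def audit_leakage(self) -> bool:
        """True iff no subject's out-of-fold score came from a model trained on it.

        Reconstructs, from the recorded fold assignments, the training set of
        the model that scored each subject (the complement of that subject's
        external fold in that repetition) and checks the scored set is
        disjoint from it, and that every subject was scored exactly once per
        repetition.
        """
        n, reps = self.oof_probabilities.shape
        if np.any(self.external_assignments < 0) or np.any(np.isnan(self.oof_probabilities)):
            return False
        for r in range(reps):
            ext = self.external_assignments[:, r]
            for k in range(self.K1):
                scored = set(np.flatnonzero(ext == k))
                trained = set(np.flatnonzero(ext != k))
                if scored & trained:
                    return False
        return True


def nested_cv_evaluate(
    X,
    y,
    grid: SearchGrid,
    K1: int = 10,
    K2: int = 10,
    repetitions: int = 100,
    base_seed: int = 0,
    tol: float = 1e-7,
    selection_rule: str = "best",
) -> CVPerformance:
    """Full nested-CV protocol with repeated random partitions.

    For each repetition and external fold, parameters are chosen by
    ``inner_select`` on the training/validation subjects only, the model is
    refitted on those subjects at the selected pair, and only the held-out
    fold is scored; every subject receives exactly one out-of-fold
    probability per repetition.
    """
    Xv = _values(X)
    y = _validate_labels(y)
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    n = len(y)
    oof = np.full((n, repetitions), np.nan)
    ext = np.full((n, repetitions), -1, dtype=int)
    rep_rows, fold_rows = [], []
    for rep in range(repetitions):
        seed_r = int(_rep_seed_sequence(base_seed, rep).generate_state(1)[0] % (2**31))
        plan = make_fold_plan(y, K1, K2, seed_r)
        ext[:, rep] = plan.external
        fold_metrics = []
        for k in range(K1):
            tr_idx = plan.training_subjects(k)
            te_idx = plan.test_subjects(k)
            inner_ids = plan.internal[k][tr_idx]
            try:
                sel = inner_select(
                    Xv[tr_idx], y[tr_idx], inner_ids, grid,
                    tol=tol, selection_rule=selection_rule,
                )
                model = fit_elastic_net_logistic(
                    Xv[tr_idx], y[tr_idx], sel.pair, tol=tol, path_length=10
                )
            except ConvergenceError as err:
                raise ConvergenceError(
                    f"solver failed in repetition {rep}, external fold {k}: {err}"
                ) from err
            prob = expit(model.intercept + Xv[te_idx] @ model.coefficients)
            oof[te_idx, rep] = prob
            m = performance_metrics(y[te_idx], (prob > 0.5).astype(int))
            fold_metrics.append(m)
            fold_rows.append(
                dict(repetition=rep, fold=k, alpha=sel.pair.alpha, lam=sel.pair.lam,
                     n_test=len(te_idx), **m)
            )
        rep_rows.append(
            dict(
                repetition=rep,
                accuracy=float(np.mean([m["accuracy"] for m in fold_metrics])),
                sensitivity=float(np.nanmean([m["sensitivity"] for m in fold_metrics])),
                specificity=float(np.nanmean([m["specificity"] for m in fold_metrics])),
            )
        )
    return CVPerformance(
        per_repetition=pd.DataFrame(rep_rows),
        fold_records=pd.DataFrame(fold_rows),
        oof_probabilities=oof,
        external_assignments=ext,
        K1=K1,
        K2=K2,
        base_seed=base_seed,
    )


def select_and_fit_full(
    X,
    y,
    grid: SearchGrid,
    K2: int = 10,
    seed: int = 0,
    tol: float = 1e-7,
    selection_rule: str = "best",
):
    """Grid-search on ALL anchor data (K2-fold) and refit on the full set.

    This is the full-model route used to score holdout (non-anchor) groups
    and to build discriminative weight ensembles: one stratified K2-fold
    partition per repetition seed drives the selection, then the model is
    refitted on every subject at the chosen pair.
    """
    Xv = _values(X)
    y = _validate_labels(y)
    state = int(np.random.SeedSequence(entropy=int(seed)).generate_state(1)[0] % (2**31))
    fold_ids = _kfold_assignment(y, K2, state)
    sel = inner_select(Xv, y, fold_ids, grid, tol=tol, selection_rule=selection_rule)
    model = fit_elastic_net_logistic(Xv, y, sel.pair, tol=tol, path_length=10)
    return sel.pair, model
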