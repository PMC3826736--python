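"""AD Pattern Similarity (AD-PS) score estimation and hypercube geometry.

An AD-PS score is the class-conditional probability P(AD-like | data) from
the regularized logistic classifier, used as a disease-similarity metric in
[0, 1]. Scores for the two anchor classes (cognitively normal = 0, AD = 1)
are taken out-of-fold in the external CV loop to avoid overfitting; scores
for intermediate (MCI) groups come from models fitted on all anchor data.
Per-modality scores place each subject inside a unit probability hypercube
whose all-ones vertex is the "AD corner"; sums of coordinates give the
anatomical (GM+WM+CSF) and cognitive-anatomical composites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy.special import expit

from .linear_model import _column_ids, _validate_labels, _values, predict_probability
from .model_selection import (
    CVPerformance,
    SearchGrid,
    _rep_seed_sequence,
    nested_cv_evaluate,
    select_and_fit_full,
)

__all__ = [
    "MODALITY_ORDER",
    "ADPSScoreSet",
    "score_anchor_classes",
    "score_holdout_group",
    "composite",
    "risk_zone",
    "risk_zones",
    "corner_distance",
    "AD_CORNER",
]

#: Fixed coordinate order of the probability hypercube.
MODALITY_ORDER = ("GM", "WM", "CSF", "cognitive")

OUT_OF_FOLD = "out_of_fold"
FULL_MODEL = "full_model"


@dataclass
class ADPSScoreSet:
    """Per-subject AD-PS scores for one modality.

    ``provenance`` records, per subject, whether the score is the median of
    out-of-fold probabilities (anchor classes) or of full-anchor-model
    probabilities (holdout groups).
    """

    modality: str
    scores: np.ndarray
    provenance: np.ndarray
    repetitions_used: int
    cv_performance: Optional[CVPerformance] = None

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if np.any((s < 0) | (s > 1)):
            raise ValueError("AD-PS scores must lie in [0, 1]")
        prov = np.asarray(self.provenance)
        if prov.shape != s.shape:
            raise ValueError("provenance must align with scores")
        if not set(np.unique(prov)) <= {OUT_OF_FOLD, FULL_MODEL}:
            raise ValueError("unknown provenance value")
        self.scores = s
        self.provenance = prov


def score_anchor_classes(
    X,
    y,
    grid: Optional[SearchGrid] = None,
    K1: int = 10,
    K2: int = 10,
    repetitions: int = 100,
    seed: int = 0,
    modality: str = "GM",
    tol: float = 1e-7,
) -> ADPSScoreSet:
    """Out-of-fold AD-PS scores for the anchor (CN=0 / AD=1) subjects.

    Each subject's score is the median, across repetitions, of the
    probability produced by the external-fold model that held it out.
    """
    if grid is None:
        grid = SearchGrid()
    perf = nested_cv_evaluate(
        X, y, grid, K1=K1, K2=K2, repetitions=repetitions, base_seed=seed, tol=tol
    )
    scores = np.median(perf.oof_probabilities, axis=1)
    return ADPSScoreSet(
        modality=modality,
        scores=np.clip(scores, 0.0, 1.0),
        provenance=np.full(len(scores), OUT_OF_FOLD, dtype=object),
        repetitions_used=repetitions,
        cv_performance=perf,
    )


def score_holdout_group(
    X_anchor,
    y_anchor,
    X_holdout,
    grid: Optional[SearchGrid] = None,
    repetitions: int = 100,
    seed: int = 0,
    K2: int = 10,
    modality: str = "GM",
    tol: float = 1e-7,
) -> ADPSScoreSet:
    """Full-model AD-PS scores for a holdout (intermediate) group.

    Per repetition a model is fitted on ALL anchor subjects at the
    regularization pair selected by that repetition's K2-fold grid search on
    the full anchor set; the holdout score is the median probability across
    repetitions.
    """
    if grid is None:
        grid = SearchGrid()
    ids_a, ids_h = _column_ids(X_anchor), _column_ids(X_holdout)
    if ids_a is not None and ids_h is not None and ids_a != ids_h:
        raise ValueError("holdout columns do not match anchor columns")
    Xa = _values(X_anchor)
    Xh = _values(X_holdout)
    if Xa.shape[1] != Xh.shape[1]:
        raise ValueError("holdout column count does not match anchors")
    y = _validate_labels(y_anchor)
    probs = np.empty((Xh.shape[0], repetitions))
    for rep in range(repetitions):
        seed_r = int(_rep_seed_sequence(seed, rep).generate_state(1)[0] % (2**31))
        _, model = select_and_fit_full(Xa, y, grid, K2=K2, seed=seed_r, tol=tol)
        probs[:, rep] = expit(model.intercept + Xh @ model.coefficients)
    scores = np.clip(np.median(probs, axis=1), 0.0, 1.0)
    return ADPSScoreSet(
        modality=modality,
        scores=scores,
        provenance=np.full(len(scores), FULL_MODEL, dtype=object),
        repetitions_used=repetitions,
    )


def _score_array(s) -> np.ndarray:
    return s.scores if isinstance(s, ADPSScoreSet) else np.asarray(s, dtype=float)


def composite(scores: Mapping[str, object], kind: str) -> np.ndarray:
    """Composite AD-PS metrics: plain sums of per-modality probabilities.

    ``anatomical`` = GM + WM + CSF (range [0, 3]);
    ``cognitive_anatomical`` = anatomical + cognitive (range [0, 4]).
    """
    if kind == "anatomical":
        needed = ("GM", "WM", "CSF")
    elif kind == "cognitive_anatomical":
        needed = ("GM", "WM", "CSF", "cognitive")
    else:
        raise ValueError("kind must be 'anatomical' or 'cognitive_anatomical'")
    missing = [m for m in needed if m not in scores]
    if missing:
        raise ValueError(f"missing modality for composite '{kind}': {missing}")
    arrays = [_score_array(scores[m]) for m in needed]
    n = {len(a) for a in arrays}
    if len(n) != 1:
        raise ValueError("modalities cover different subject sets")
    return np.sum(arrays, axis=0)


def hypercube_points(scores: Mapping[str, object]) -> np.ndarray:
    """Stack per-modality scores into (n, D) points in MODALITY_ORDER."""
    present = [m for m in MODALITY_ORDER if m in scores]
    return np.column_stack([_score_array(scores[m]) for m in present])


def risk_zone(point, threshold: float = 0.5) -> str:
    """'low' iff every coordinate < threshold, 'high' iff every > threshold,
    else 'indeterminate' (coordinates exactly at the threshold included)."""
    p = np.asarray(point, dtype=float)
    if np.all(p < threshold):
        return "low"
    if np.all(p > threshold):
        return "high"
    return "indeterminate"


def risk_zones(points, threshold: float = 0.5) -> np.ndarray:
    """Vectorized risk_zone over an (n, D) array of hypercube points."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.full(P.shape[0], "indeterminate", dtype=object)
    out[np.all(P < threshold, axis=1)] = "low"
    out[np.all(P > threshold, axis=1)] = "high"
    return out


#: The all-ones vertex of the 4-D hypercube (GM, WM, CSF, cognitive).
AD_CORNER = np.ones(len(MODALITY_ORDER))


def corner_distance(point, corner) -> float:
    """Euclidean distance from a hypercube point to a corner (in [0, sqrt(D)])."""
    p = np.asarray(point, dtype=float)
    c = np.asarray(corner, dtype=float)
    if p.shape != c.shape:
        raise ValueError("corner dimension must match point dimension")
    return float(np.linalg.norm(p - c))
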