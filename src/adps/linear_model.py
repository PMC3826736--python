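"""Sparse logistic regression with the elastic-net penalty.

This is the classifier behind the AD Pattern Similarity (AD-PS) scores: a
binary logistic model fitted directly on very high dimensional feature
matrices (one column per voxel of a masked tissue map, or per cognitive
score), regularized so that the weight vector is sparse.

The fitted objective is

    argmin_{b0, beta}  (1/n) * sum_i log(1 + exp(-(2 y_i - 1)(b0 + x_i . beta)))
                       + lam * ( alpha * ||beta||_1 + (1 - alpha)/2 * ||beta||_2^2 )

with the intercept ``b0`` never penalized. ``alpha`` mixes the L1 (sparsity)
and L2 (grouping) penalty parts; ``lam`` sets the overall penalty strength.

The optimizer is an iteratively reweighted least-squares (IRLS) outer loop
with coordinate-wise soft-threshold updates on the working quadratic — the
standard solver family for this objective. Predictors are centered and
scaled to unit variance internally by default and coefficients are mapped
back to the original scale; convergence is declared on the subgradient
(KKT) optimality conditions of the true objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy.special import expit

__all__ = [
    "FeatureMatrix",
    "RegularizationPair",
    "ElasticNetModel",
    "ConvergenceError",
    "fit_elastic_net_logistic",
    "enet_logistic_path",
    "elastic_net_wls",
    "lambda_max",
    "predict_probability",
    "classify",
    "kkt_residual",
]

_PROB_CLIP = 1e-10       # probability floor for log-likelihood evaluation
_SAT = 1e-5              # IRLS saturation threshold on fitted probabilities
_PRED_CLIP = 1e-12       # keeps predicted probabilities strictly inside (0, 1)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FeatureMatrix:
    """Subjects-by-variables design matrix for one modality.

    ``variable_kind`` is ``"voxel"`` for vectorized tissue maps and
    ``"cognitive"`` for test batteries; ``column_ids`` are voxel linear
    indices within a mask or cognitive score names.
    """

    values: np.ndarray
    column_ids: tuple
    variable_kind: str = "voxel"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("FeatureMatrix values must be 2-D")
        n, p = values.shape
        if n < 1 or p < 1:
            raise ValueError("FeatureMatrix needs >= 1 subject and >= 1 variable")
        if not np.all(np.isfinite(values)):
            raise ValueError("FeatureMatrix contains missing or non-finite values")
        ids = tuple(self.column_ids)
        if len(ids) != p:
            raise ValueError("column_ids length must match the number of columns")
        if len(set(ids)) != p:
            raise ValueError("column_ids must be unique")
        if self.variable_kind not in ("voxel", "cognitive"):
            raise ValueError("variable_kind must be 'voxel' or 'cognitive'")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "column_ids", ids)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]


def as_feature_matrix(X, variable_kind: str = "voxel") -> FeatureMatrix:
    """Coerce a plain array to a FeatureMatrix with positional column ids."""
    if isinstance(X, FeatureMatrix):
        return X
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(X, tuple(range(X.shape[1])), variable_kind)


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def _column_ids(X) -> Optional[tuple]:
    return X.column_ids if isinstance(X, FeatureMatrix) else None


@dataclass(frozen=True)
class RegularizationPair:
    """Elastic-net mixing weight ``alpha`` in [0, 1] and strength ``lam`` >= 0."""

    alpha: float
    lam: float

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.lam < 0.0:
            raise ValueError("lam must be non-negative")


@dataclass
class ElasticNetModel:
    """Fitted sparse logistic model (coefficients on the original scale)."""

    intercept: float
    coefficients: np.ndarray
    regularization: RegularizationPair
    converged: bool
    objective_value: float
    kkt_residual: float
    n_iter: int
    column_ids: Optional[tuple] = None
    standardized: bool = True

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def to_dict(self) -> dict:
        """Plain-container serialization (sparse coefficient triplets)."""
        nz = np.flatnonzero(self.coefficients)
        ids = self.column_ids if self.column_ids is not None else tuple(range(len(self.coefficients)))
        return {
            "intercept": float(self.intercept),
            "n_variables": int(len(self.coefficients)),
            "column_ids": list(ids),
            "coefficients": [[ids[j], float(self.coefficients[j])] for j in nz],
            "alpha": self.regularization.alpha,
            "lam": self.regularization.lam,
            "converged": bool(self.converged),
            "objective_value": float(self.objective_value),
            "standardized": bool(self.standardized),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ElasticNetModel":
        ids = list(data["column_ids"])
        pos = {cid: j for j, cid in enumerate(ids)}
        coef = np.zeros(data["n_variables"])
        for cid, value in data["coefficients"]:
            coef[pos[cid]] = value
        return cls(
            intercept=float(data["intercept"]),
            coefficients=coef,
            regularization=RegularizationPair(data["alpha"], data["lam"]),
            converged=bool(data["converged"]),
            objective_value=float(data["objective_value"]),
            kkt_residual=float("nan"),
            n_iter=0,
            column_ids=tuple(ids),
            standardized=bool(data["standardized"]),
        )


class ConvergenceError(RuntimeError):
    """Raised when the solver exhausts max_iter; carries partial diagnostics."""

    def __init__(self, message: str, model: Optional[ElasticNetModel] = None):
        super().__init__(message)
        self.model = model


# ---------------------------------------------------------------------------
# numerical core


@njit(cache=True)
def _cd_quadratic(XA, w, r, beta, b0, lam1, lam2, tol, max_sweeps):  # pragma: no cover
    """Coordinate descent on a penalized weighted least-squares problem.

    Minimizes (1/2n) sum_i w_i (r_i + offset)^2 style working objective in
    place: ``r`` holds the current working residual, ``beta`` the active
    coefficients. Returns (b0, sweeps, max_last_delta).
    """
    n, k = XA.shape
    sw = 0.0
    for i in range(n):
        sw += w[i]
    v = np.empty(k)
    for j in range(k):
        s = 0.0
        for i in range(n):
            s += w[i] * XA[i, j] * XA[i, j]
        v[j] = s / n
    sweeps = 0
    dmax = 0.0
    while sweeps < max_sweeps:
        sweeps += 1
        dmax = 0.0
        for j in range(k):
            bj = beta[j]
            g = 0.0
            for i in range(n):
                g += w[i] * XA[i, j] * r[i]
            g = g / n + v[j] * bj
            if g > lam1:
                bn = (g - lam1) / (v[j] + lam2)
            elif g < -lam1:
                bn = (g + lam1) / (v[j] + lam2)
            else:
                bn = 0.0
            d = bn - bj
            if d != 0.0:
                beta[j] = bn
                for i in range(n):
                    r[i] -= XA[i, j] * d
                if abs(d) > dmax:
                    dmax = abs(d)
        gi = 0.0
        for i in range(n):
            gi += w[i] * r[i]
        d0 = gi / sw
        if d0 != 0.0:
            b0 += d0
            for i in range(n):
                r[i] -= d0
            if abs(d0) > dmax:
                dmax = abs(d0)
        if dmax < tol:
            break
    return b0, sweeps, dmax


def _standardize(X: np.ndarray, standardize: bool):
    if not standardize:
        p = X.shape[1]
        return X, np.zeros(p), np.ones(p)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)  # population (1/n) convention
    scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def _objective(Xs, y, beta, b0, alpha, lam, active_idx=None):
    """Penalized objective on the fitting scale (mean negative log-likelihood)."""
    if active_idx is None:
        eta = b0 + Xs @ beta
    else:
        eta = b0 + Xs[:, active_idx] @ beta[active_idx]
    p = np.clip(expit(eta), _PROB_CLIP, 1.0 - _PROB_CLIP)
    loss = -np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    penalty = lam * (alpha * np.abs(beta).sum() + 0.5 * (1.0 - alpha) * (beta ** 2).sum())
    return loss + penalty


def _kkt_on_scaled(Xs, y, beta, b0, alpha, lam):
    """Per-coordinate KKT residuals of the true objective on the fitting scale."""
    n = Xs.shape[0]
    eta = b0 + Xs @ beta
    pb = expit(eta)
    g = Xs.T @ (pb - y) / n + lam * (1.0 - alpha) * beta
    lam1 = lam * alpha
    res = np.where(
        beta != 0.0,
        np.abs(g + lam1 * np.sign(beta)),
        np.maximum(0.0, np.abs(g) - lam1),
    )
    res0 = abs(float(np.mean(pb - y)))
    return res, res0, g


def _fit_scaled(Xs, y, alpha, lam, tol, max_iter, beta=None, b0=0.0):
    """IRLS + coordinate descent on standardized predictors.

    Returns (beta, b0, total_sweeps, kkt_max, converged).
    """
    n, p = Xs.shape
    if beta is None:
        beta = np.zeros(p)
    else:
        beta = beta.copy()
    lam1 = lam * alpha
    lam2 = lam * (1.0 - alpha)
    # With no L1 part every coordinate can move; start them all active.
    active = (beta != 0.0) if lam1 > 0.0 else np.ones(p, dtype=bool)
    total_sweeps = 0
    cd_tol = tol * 0.1
    kkt_max = np.inf
    sat = _SAT
    for _outer in range(200):
        # IRLS to a fixed point on the current active set; each Newton step
        # is safeguarded by halving toward the previous iterate whenever the
        # true penalized objective fails to decrease (proximal-Newton line
        # search), which keeps the loop stable when probabilities saturate.
        idx = np.flatnonzero(active)
        XA = np.asfortranarray(Xs[:, idx])
        bA = beta[idx].copy()

        def _obj_active(bvec, icpt):
            eta = icpt + XA @ bvec
            pc = np.clip(expit(eta), _PROB_CLIP, 1.0 - _PROB_CLIP)
            loss = -np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))
            pen = lam * (alpha * np.abs(bvec).sum() + 0.5 * (1.0 - alpha) * (bvec ** 2).sum())
            return loss + pen

        obj_cur = _obj_active(bA, b0)
        for _irls in range(100):
            eta = b0 + XA @ bA
            pb = expit(eta)
            # saturation rule of the coordinate-descent solver family:
            # probabilities within `sat` of 0/1 are snapped there and their
            # working weight floored, which bounds the working response
            lo = pb < sat
            hi = pb > 1.0 - sat
            w = pb * (1.0 - pb)
            w[lo | hi] = sat
            pz = np.where(hi, 1.0, np.where(lo, 0.0, pb))
            r = (y - pz) / w
            b0_prev = b0
            bA_prev = bA.copy()
            b0, sweeps, _ = _cd_quadratic(
                XA, w, r, bA, b0, lam1, lam2, cd_tol, max(10, max_iter - total_sweeps)
            )
            total_sweeps += sweeps
            obj_new = _obj_active(bA, b0)
            halvings = 0
            while not (obj_new <= obj_cur + 1e-14) and halvings < 40:
                bA = 0.5 * (bA + bA_prev)
                b0 = 0.5 * (b0 + b0_prev)
                obj_new = _obj_active(bA, b0)
                halvings += 1
            obj_cur = obj_new
            delta = abs(b0 - b0_prev)
            if bA.size:
                delta = max(delta, float(np.max(np.abs(bA - bA_prev))))
            if total_sweeps >= max_iter:
                beta[idx] = bA
                return beta, b0, total_sweeps, kkt_max, False
            if delta < tol:
                break
        beta[idx] = bA
        # KKT screen on the full coordinate set at the true probabilities
        res, res0, _ = _kkt_on_scaled(Xs, y, beta, b0, alpha, lam)
        kkt_max = max(float(res.max(initial=0.0)), res0)
        violators = (~active) & (res > tol)
        if kkt_max <= tol:
            return beta, b0, total_sweeps, kkt_max, True
        if violators.any():
            active |= violators
        elif sat > 1e-8:
            # IRLS is at its snapped fixed point but the snap bias keeps the
            # true KKT residual above tol: polish with a tighter snap
            sat = 1e-8
        # else: iterate IRLS further at the tight snap
    return beta, b0, total_sweeps, kkt_max, False


def _validate_labels(y) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    vals = np.unique(y)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("labels must be coded 0/1")
    if vals.size < 2:
        raise ValueError("both classes must be present to fit a classifier")
    return y


def fit_elastic_net_logistic(
    X,
    y,
    reg: RegularizationPair,
    tol: float = 1e-7,
    max_iter: int = 10_000,
    standardize: bool = True,
    path_length: int = 0,
) -> ElasticNetModel:
    """Fit the elastic-net penalized logistic regression.

    Parameters
    ----------
    X : FeatureMatrix or (n, p) array
    y : 0/1 labels, both classes present
    reg : RegularizationPair (alpha, lam)
    tol : KKT residual tolerance declaring convergence (per coordinate)
    max_iter : cap on total coordinate-descent sweeps
    standardize : center/scale columns internally; coefficients are always
        returned on the original scale.
    path_length : if > 0, warm-start the fit through this many log-spaced
        penalty values from lambda_max down to ``reg.lam`` instead of
        starting cold — the standard pathwise strategy, much faster and more
        stable at small lam on p >> n data. The returned solution satisfies
        the same KKT tolerance either way.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    Xv = _values(X)
    y = _validate_labels(y)
    if Xv.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of subjects")
    Xs, mean, scale = _standardize(Xv, standardize)
    beta0, b00 = None, 0.0
    if path_length > 1 and reg.alpha > 0 and reg.lam > 0:
        n = Xs.shape[0]
        lmax = float(np.max(np.abs(Xs.T @ (y - y.mean()) / n)) / reg.alpha)
        if lmax > reg.lam:
            beta0 = np.zeros(Xs.shape[1])
            b00 = float(np.log(y.mean() / (1.0 - y.mean())))
            warm_tol = max(tol, 1e-6)
            for lam_k in np.geomspace(lmax, reg.lam, path_length)[:-1]:
                beta0, b00, _, _, _ = _fit_scaled(
                    Xs, y, reg.alpha, float(lam_k), warm_tol, max_iter,
                    beta=beta0, b0=b00,
                )
    beta, b0, sweeps, kkt, converged = _fit_scaled(
        Xs, y, reg.alpha, reg.lam, tol, max_iter, beta=beta0, b0=b00
    )
    obj = _objective(Xs, y, beta, b0, reg.alpha, reg.lam)
    coef = beta / scale
    intercept = b0 - float((mean / scale) @ beta)
    model = ElasticNetModel(
        intercept=intercept,
        coefficients=coef,
        regularization=reg,
        converged=converged,
        objective_value=float(obj),
        kkt_residual=float(kkt),
        n_iter=sweeps,
        column_ids=_column_ids(X),
        standardized=standardize,
    )
    if not converged:
        raise ConvergenceError(
            f"elastic-net solver did not reach tol={tol:g} within "
            f"max_iter={max_iter} sweeps (KKT residual {kkt:.3e})",
            model=model,
        )
    return model


def enet_logistic_path(
    X,
    y,
    alpha: float,
    lams: Sequence[float],
    tol: float = 1e-7,
    max_iter: int = 10_000,
    standardize: bool = True,
):
    """Warm-started fits along a decreasing lambda path at fixed alpha.

    Returns ``(intercepts, coefs)`` with ``coefs`` of shape (p, len(lams)),
    both on the original feature scale.

    Following the coordinate-descent solver family's convention, the path
    stops early once the fitted model explains essentially all of the null
    deviance (ratio > 0.999, i.e. the classes are separated) or once a
    bottom-of-path fit fails to stabilize (complete separation with a
    vanishing penalty has no usable solution); the remaining path entries
    repeat the last stable solution, whose predictions the still-smaller
    penalties would not materially change. A failure at the very first
    (heaviest) penalty is a genuine error and raises.
    """
    Xv = _values(X)
    y = _validate_labels(y)
    lams = np.asarray(lams, dtype=float)
    if lams.size == 0:
        raise ValueError("empty lambda path")
    if np.any(np.diff(lams) >= 0):
        raise ValueError("lambda path must be strictly decreasing")
    Xs, mean, scale = _standardize(Xv, standardize)
    p = Xs.shape[1]
    coefs = np.empty((p, lams.size))
    intercepts = np.empty(lams.size)
    beta = np.zeros(p)
    b0 = float(np.log(y.mean() / (1.0 - y.mean())))
    null_dev = _objective(Xs, y, np.zeros(p), b0, alpha, 0.0)
    for k, lam in enumerate(lams):
        beta, b0, _, kkt, converged = _fit_scaled(
            Xs, y, alpha, float(lam), tol, max_iter, beta=beta, b0=b0
        )
        if not converged:
            if k == 0:
                raise ConvergenceError(
                    f"path fit failed at lam={lam:g} (KKT residual {kkt:.3e})"
                )
            for j in range(k, lams.size):
                coefs[:, j] = coefs[:, k - 1]
                intercepts[j] = intercepts[k - 1]
            break
        coefs[:, k] = beta / scale
        intercepts[k] = b0 - float((mean / scale) @ beta)
        dev = _objective(Xs, y, beta, b0, alpha, 0.0)
        if null_dev > 0 and 1.0 - dev / null_dev > 0.999:
            for j in range(k + 1, lams.size):
                coefs[:, j] = coefs[:, k]
                intercepts[j] = intercepts[k]
            break
    return intercepts, coefs


def elastic_net_wls(X, y, weights, alpha, lam, tol=1e-10, max_sweeps=10_000):
    """Elastic-net penalized weighted least squares by coordinate descent.

    Solves  argmin (1/2n) sum_i w_i (y_i - b0 - x_i.beta)^2
                  + lam (alpha ||beta||_1 + (1-alpha)/2 ||beta||_2^2)

    on the given (unstandardized) design. This exposes the quadratic core
    the logistic solver iterates on; on an orthonormal design it reduces to
    the closed-form soft-threshold solution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    n, p = X.shape
    beta = np.zeros(p)
    b0 = 0.0
    r = y.copy()
    XA = np.asfortranarray(X)
    b0, _, _ = _cd_quadratic(
        XA, w, r, beta, b0, lam * alpha, lam * (1.0 - alpha), tol, max_sweeps
    )
    return b0, beta


def lambda_max(X, y, alpha: float, standardize: bool = True) -> float:
    """Smallest penalty strength at which all coefficients are exactly zero.

    At the all-zero solution the intercept is the log-odds of mean(y) and the
    score of column j is x_j . (y - mean(y)) / n; the KKT bound is the largest
    absolute score divided by alpha.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive (no finite threshold at alpha = 0)")
    Xv = _values(X)
    y = _validate_labels(y)
    Xs, _, _ = _standardize(Xv, standardize)
    n = Xs.shape[0]
    score = Xs.T @ (y - y.mean()) / n
    return float(np.max(np.abs(score)) / alpha)


def predict_probability(model: ElasticNetModel, X) -> np.ndarray:
    """Per-subject P(class 1 | x) = logistic(intercept + x . coefficients)."""
    ids = _column_ids(X)
    if ids is not None and model.column_ids is not None and ids != tuple(model.column_ids):
        raise ValueError("FeatureMatrix columns do not match the model's training columns")
    Xv = _values(X)
    if Xv.shape[1] != model.coefficients.shape[0]:
        raise ValueError("column count does not match the model")
    eta = model.intercept + Xv @ model.coefficients
    return np.clip(expit(eta), _PRED_CLIP, 1.0 - _PRED_CLIP)


def classify(probabilities, threshold: float = 0.5) -> np.ndarray:
    """Label 1 iff probability > threshold; ties at the threshold go to 0."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p > threshold).astype(int)


def kkt_residual(model: ElasticNetModel, X, y) -> float:
    """Max per-coordinate KKT residual of a fitted model on its training data.

    Evaluated on the same (standardized or raw) scale the model was fitted on.
    """
    Xv = _values(X)
    y = _validate_labels(y)
    Xs, mean, scale = _standardize(Xv, model.standardized)
    beta = model.coefficients * scale
    b0 = model.intercept + float((mean / scale) @ beta)
    res, res0, _ = _kkt_on_scaled(
        Xs, y, beta, b0, model.regularization.alpha, model.regularization.lam
    )
    return max(float(res.max(initial=0.0)), res0)
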