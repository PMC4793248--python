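"""Treatment-mechanism and outcome-regression fits, two ways.

Every downstream stage (matching, weighting, g-computation, TMLE) consumes a
propensity model ``g(W) = P(A = 1 | W)`` and/or an outcome model
``Qbar(A, W) = E[Y | A, W]``.  These are fit either

- *parametrically*: main-terms-only linear/logistic regression.  On the
  packaged simulation scenarios this is deliberately misspecified (the true
  mechanisms contain squares and interactions), mirroring what happens in
  practice when the functional form is assumed; or
- *semi-parametrically*: a cross-validated convex-stacking ensemble (super
  learner) over a small library of learners.  V-fold cross-validation
  produces out-of-fold predictions per learner, the stacking weights minimise
  the weighted CV loss over the probability simplex, and the final predictor
  is the convex combination of the learners refit on all data.

All fits accept nonnegative observation weights and are invariant to
rescaling the weights by a positive constant.  Fitted propensities are
truncated to ``DEFAULT_PS_BOUNDS`` before they leave this module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr as _pivoted_qr
from scipy.optimize import minimize
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.preprocessing import PolynomialFeatures

from .synthetic import StudyData

__all__ = [
    "PropensityFit",
    "OutcomeFit",
    "EnsembleSpec",
    "DEFAULT_PS_BOUNDS",
    "fit_propensity_parametric",
    "fit_outcome_parametric",
    "fit_ensemble",
    "stack_weights",
    "LEARNER_REGISTRY",
]

logger = logging.getLogger(__name__)

#: Truncation applied to every fitted propensity: keeps inverse-probability
#: and TMLE clever-covariate weights bounded in near-positivity-violation
#: samples.
DEFAULT_PS_BOUNDS = (0.005, 0.995)


def _norm_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights length mismatch")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and nonnegative")
    tot = w.sum()
    if tot <= 0:
        raise ValueError("weights must have positive total")
    # scale invariance: normalise to mean 1
    return w * (n / tot)


@dataclass
class PropensityFit:
    """A fitted treatment mechanism with truncated predictions."""

    fitted_ps: np.ndarray
    method: str  # "parametric" | "ensemble"
    bounds: tuple[float, float] = DEFAULT_PS_BOUNDS
    predictor: "object" = None  # callable: covariate matrix -> probabilities
    params: np.ndarray | None = None
    bse: np.ndarray | None = None
    converged_at_bound: bool = False
    stack: dict | None = None

    def predict(self, X) -> np.ndarray:
        p = self.predictor(np.asarray(X, dtype=float))
        return np.clip(p, self.bounds[0], self.bounds[1])


@dataclass
class OutcomeFit:
    """A fitted outcome regression ``Qbar(A, W)``."""

    method: str
    predictor: "object" = None  # callable: (covariate matrix, treatment) -> mean
    fitted: np.ndarray | None = None
    params: np.ndarray | None = None
    stack: dict | None = None

    def predict(self, X, a) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        a = np.broadcast_to(np.asarray(a, dtype=float), (X.shape[0],))
        out = self.predictor(X, a)
        if not np.all(np.isfinite(out)):
            raise ValueError("outcome predictions are non-finite")
        return out


# ---------------------------------------------------------------------------
# Parametric fits (main terms only)
# ---------------------------------------------------------------------------


def fit_propensity_parametric(
    data: StudyData,
    weights=None,
    bounds: tuple[float, float] = DEFAULT_PS_BOUNDS,
) -> PropensityFit:
    """Weighted ML logistic regression of A on main terms of W.

    No squares or interactions are included, so on the packaged scenarios the
    fit is misspecified by design.  Under perfect separation the fit is
    flagged ``converged_at_bound`` and predictions are still truncated.
    """
    import statsmodels.api as sm

    w = _norm_weights(weights, data.n)
    a = data.treatment
    for arm in (0, 1):
        if w[a == arm].sum() <= 0:
            raise ValueError(f"treatment class {arm} has zero total weight")
    X = sm.add_constant(data.X, has_constant="add")
    at_bound = False
    params = bse = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.GLM(a, X, family=sm.families.Binomial(), var_weights=w)
            res = model.fit(maxiter=200)
            params = np.asarray(res.params)
            bse = np.asarray(res.bse)
            if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e3:
                raise ValueError("divergent coefficients")
        except Exception:  # perfect separation or non-convergence
            at_bound = True
            clf = LogisticRegression(C=1e4, max_iter=2000)
            clf.fit(data.X, a, sample_weight=w)
            params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
            bse = None
    beta = params

    def predictor(Xnew):
        eta = beta[0] + np.asarray(Xnew, dtype=float) @ beta[1:]
        return 1.0 / (1.0 + np.exp(-eta))

    fit = PropensityFit(
        fitted_ps=np.clip(predictor(data.X), bounds[0], bounds[1]),
        method="parametric",
        bounds=bounds,
        predictor=predictor,
        params=params,
        bse=bse,
        converged_at_bound=at_bound,
    )
    if at_bound:
        logger.warning("propensity fit converged at bound (possible separation)")
    return fit


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by pivoted QR
        _, _, piv = _pivoted_qr(design, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_outcome_parametric(data: StudyData, weights=None) -> OutcomeFit:
    """Weighted least squares of Y on (A, main terms of W)."""
    w = _norm_weights(weights, data.n)
    X = np.column_stack([np.ones(data.n), data.treatment, data.X])
    names = ["const", "A", *list(data.covariates.columns)]
    _check_rank(X, names)
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], data.outcome * sw, rcond=None)

    def predictor(Xnew, a):
        Xnew = np.asarray(Xnew, dtype=float)
        a = np.broadcast_to(np.asarray(a, dtype=float), (Xnew.shape[0],))
        return beta[0] + beta[1] * a + Xnew @ beta[2:]

    fitted = predictor(data.X, data.treatment)
    return OutcomeFit(method="parametric", predictor=predictor, fitted=fitted, params=beta)


# ---------------------------------------------------------------------------
# Super-learner ensemble
# ---------------------------------------------------------------------------


class _Learner:
    """Adapter giving every library member fit/predict with weights."""

    def __init__(self, name: str, est, expand: bool = False, weighted: bool = True):
        self.name = name
        self.est = est
        self.expand = expand
        self.weighted = weighted
        self._poly = None

    def _features(self, X):
        if not self.expand:
            return X
        if self._poly is None:
            self._poly = PolynomialFeatures(degree=2, include_bias=False)
            self._poly.fit(X)
        return self._poly.transform(X)

    def fit(self, X, y, sample_weight):
        F = self._features(X)
        if self.weighted:
            self.est.fit(F, y, sample_weight=sample_weight)
        else:
            self.est.fit(F, y)
        return self

    def predict(self, X):
        F = self._features(X)
        if hasattr(self.est, "predict_proba"):
            return self.est.predict_proba(F)[:, 1]
        return self.est.predict(F)


def _make_learner(name: str, task: str, seed: int, n_train: int) -> _Learner:
    cls = task == "classification"
    if name == "glm":
        est = LogisticRegression(C=np.inf, max_iter=2000) if cls else LinearRegression()
        return _Learner(name, est)
    if name == "glm_interactions":
        est = LogisticRegression(C=np.inf, max_iter=2000) if cls else LinearRegression()
        return _Learner(name, est, expand=True)
    if name == "bagged_trees":
        kw = dict(n_estimators=60, min_samples_leaf=5, random_state=seed)
        est = RandomForestClassifier(**kw) if cls else RandomForestRegressor(**kw)
        return _Learner(name, est)
    if name == "gbm":
        kw = dict(n_estimators=100, max_depth=2, learning_rate=0.1, random_state=seed)
        est = GradientBoostingClassifier(**kw) if cls else GradientBoostingRegressor(**kw)
        return _Learner(name, est)
    if name == "knn":
        k = max(1, min(25, n_train // 5))
        est = KNeighborsClassifier(n_neighbors=k) if cls else KNeighborsRegressor(n_neighbors=k)
        # kNN has no sample_weight support; fit is unweighted (documented)
        return _Learner(name, est, weighted=False)
    raise KeyError(f"unknown learner {name!r}")


#: Names resolvable by :func:`fit_ensemble`.
LEARNER_REGISTRY = ("glm", "glm_interactions", "bagged_trees", "gbm", "knn")


@dataclass
class EnsembleSpec:
    """Configuration of the cross-validated stacking ensemble."""

    learners: tuple = LEARNER_REGISTRY
    folds: int = 10
    seed: int = 0
    loss: str | None = None  # None -> log_loss for treatment, squared for outcome

    def __post_init__(self):
        self.learners = tuple(self.learners)
        if len(self.learners) < 1:
            raise ValueError("need at least one learner")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        unknown = [l for l in self.learners if l not in LEARNER_REGISTRY]
        if unknown:
            raise KeyError(f"unknown learner(s) {unknown}; registry: {LEARNER_REGISTRY}")


def _loss_value(pred: np.ndarray, y: np.ndarray, w: np.ndarray, loss: str) -> float:
    if loss == "squared_error":
        return float(np.sum(w * (y - pred) ** 2) / np.sum(w))
    if loss == "log_loss":
        p = np.clip(pred, 1e-12, 1 - 1e-12)
        return float(-np.sum(w * (y * np.log(p) + (1 - y) * np.log1p(-p))) / np.sum(w))
    raise ValueError(f"unknown loss {loss!r}")


def stack_weights(oof_predictions, observed, weights=None, loss: str = "squared_error") -> np.ndarray:
    """Convex stacking weights: argmin of weighted loss over the L-simplex.

    Identical prediction columns are collapsed before optimisation and the
    solved weight is split equally among the duplicates (the deterministic
    tie rule).  The returned vector always attains a loss no worse than any
    single column's.
    """
    P = np.asarray(oof_predictions, dtype=float)
    if P.ndim != 2 or P.shape[1] < 1:
        raise ValueError("oof_predictions must be an n x L matrix with L >= 1")
    if not np.all(np.isfinite(P)):
        raise ValueError("non-finite out-of-fold predictions")
    y = np.asarray(observed, dtype=float)
    w = _norm_weights(weights, len(y))
    L = P.shape[1]
    # collapse duplicate columns
    uniq, inverse = np.unique(P.round(12), axis=1, return_inverse=True)
    inverse = np.asarray(inverse).ravel()
    U = uniq.shape[1]
    group_sizes = np.bincount(inverse, minlength=U)

    def objective(b):
        return _loss_value(uniq @ b, y, w, loss)

    candidates = [np.full(U, 1.0 / U)]
    candidates.extend(np.eye(U))
    x0 = min(candidates, key=objective)
    if U > 1:
        res = minimize(
            objective,
            x0,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * U,
            constraints=[{"type": "eq", "fun": lambda b: b.sum() - 1.0}],
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if res.success and np.all(np.isfinite(res.x)):
            xr = np.clip(res.x, 0, None)
            xr = xr / xr.sum()
            candidates.append(xr)
        b_u = min(candidates, key=objective)
    else:
        b_u = np.ones(1)
    # expand back, splitting each unique column's weight equally among dups
    b = np.zeros(L)
    for j in range(L):
        b[j] = b_u[inverse[j]] / group_sizes[inverse[j]]
    return b


def fit_ensemble(
    data: StudyData,
    target: str,
    weights=None,
    spec: EnsembleSpec | None = None,
    bounds: tuple[float, float] = DEFAULT_PS_BOUNDS,
):
    """Fit the super-learner ensemble for ``target`` in {"treatment", "outcome"}.

    Returns a :class:`PropensityFit` (treatment) or :class:`OutcomeFit`
    (outcome).  Fold assignment is seeded from ``spec.seed`` and stratified by
    treatment when the treatment mechanism is the target.  A learner that
    raises on any fold is dropped with a logged warning; if all learners fail
    an error is raised.
    """
    spec = spec or EnsembleSpec()
    if target not in ("treatment", "outcome"):
        raise ValueError("target must be 'treatment' or 'outcome'")
    w = _norm_weights(weights, data.n)
    if data.n < 5 * spec.folds:
        raise ValueError(f"need n >= 5*V = {5 * spec.folds}, got {data.n}")
    task = "classification" if target == "treatment" else "regression"
    loss = spec.loss or ("log_loss" if target == "treatment" else "squared_error")
    if target == "treatment":
        X = data.X
        y = data.treatment
        splitter = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
        split_iter = splitter.split(X, y)
    else:
        X = np.column_stack([data.treatment.astype(float), data.X])
        y = data.outcome
        splitter = KFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
        split_iter = splitter.split(X)
    folds = list(split_iter)

    oof = {}
    for li, name in enumerate(spec.learners):
        pred = np.empty(data.n)
        try:
            for train, test in folds:
                lr = _make_learner(name, task, spec.seed + 1000 * li, len(train))
                lr.fit(X[train], y[train], w[train])
                pred[test] = lr.predict(X[test])
            if not np.all(np.isfinite(pred)):
                raise ValueError("non-finite out-of-fold predictions")
        except Exception as exc:
            logger.warning("learner %r failed in cross-validation and was dropped: %s", name, exc)
            continue
        if task == "classification":
            pred = np.clip(pred, 1e-6, 1 - 1e-6)
        oof[name] = pred
    if not oof:
        raise RuntimeError("every learner in the ensemble library failed")

    names = list(oof)
    P = np.column_stack([oof[n] for n in names])
    b = stack_weights(P, y, w, loss)
    cv_risks = {n: _loss_value(P[:, j], y, w, loss) for j, n in enumerate(names)}
    ensemble_risk = _loss_value(P @ b, y, w, loss)

    full = []
    for li, name in enumerate(names):
        lr = _make_learner(name, task, spec.seed + 1000 * spec.learners.index(name), data.n)
        lr.fit(X, y, w)
        full.append(lr)
    stack_info = {
        "learners": names,
        "weights": dict(zip(names, b.tolist())),
        "cv_risks": cv_risks,
        "ensemble_cv_risk": ensemble_risk,
        "loss": loss,
    }

    if target == "treatment":

        def predictor(Xnew):
            Xnew = np.asarray(Xnew, dtype=float)
            return sum(bi * lr.predict(Xnew) for bi, lr in zip(b, full))

        return PropensityFit(
            fitted_ps=np.clip(predictor(data.X), bounds[0], bounds[1]),
            method="ensemble",
            bounds=bounds,
            predictor=predictor,
            stack=stack_info,
        )

    def predictor(Xnew, a):
        Xnew = np.asarray(Xnew, dtype=float)
        a = np.broadcast_to(np.asarray(a, dtype=float), (Xnew.shape[0],))
        F = np.column_stack([a, Xnew])
        return sum(bi * lr.predict(F) for bi, lr in zip(b, full))

    fitted = predictor(data.X, data.treatment)
    return OutcomeFit(method="ensemble", predictor=predictor, fitted=fitted, stack=stack_info)
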