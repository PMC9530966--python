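"""Cross-validated stacking ("super learner") over a small candidate library.

The ensemble computes held-out predictions for every candidate on V folds,
finds the convex combination (non-negative weights summing to one) that
minimises the cross-validated loss, and refits the weighted candidates on
the full data. Squared loss is the default because the sequential
regressions downstream have continuous pseudo-outcomes in (and occasionally
outside) [0, 1]; log loss is available for binary targets.

Registry: ``intercept_only``, ``linear_additive``, ``gradient_boosted_trees``,
``k_nearest_neighbors`` and ``saturated`` (exact stratum means for discrete
covariates, used by the oracle-equivalence checks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.ensemble import (HistGradientBoostingClassifier,
                              HistGradientBoostingRegressor)
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.neighbors import KNeighborsRegressor

__all__ = ["LearnerSpec", "SuperLearner", "fit_superlearner", "LEARNER_REGISTRY"]

LEARNER_REGISTRY = ("intercept_only", "linear_additive",
                    "gradient_boosted_trees", "k_nearest_neighbors",
                    "saturated")

_EPS = 1e-7


@dataclass
class LearnerSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)
    loss: str = "squared"

    def __post_init__(self) -> None:
        if self.name not in LEARNER_REGISTRY:
            raise ValueError(f"unknown learner {self.name!r}; "
                             f"registry: {LEARNER_REGISTRY}")
        if self.loss not in ("squared", "log"):
            raise ValueError("loss must be 'squared' or 'log'")


def _as_spec(learner, loss: str) -> LearnerSpec:
    if isinstance(learner, LearnerSpec):
        return learner
    return LearnerSpec(str(learner), loss=loss)


class _Intercept:
    def fit(self, X, y, w=None):
        self.mean_ = float(np.average(y, weights=w))
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


class _Saturated:
    """Weighted mean of the target within each unique covariate row."""

    def fit(self, X, y, w=None):
        X = np.asarray(X, dtype=float)
        w = np.ones(len(X)) if w is None else np.asarray(w, dtype=float)
        keys, inv = np.unique(X, axis=0, return_inverse=True)
        num = np.bincount(inv, weights=w * np.asarray(y, dtype=float))
        den = np.bincount(inv, weights=w)
        means = num / np.maximum(den, 1e-300)
        self.table_ = {k.tobytes(): m for k, m in zip(keys, means)}
        self.default_ = float(np.average(y, weights=w))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return np.array([self.table_.get(row.tobytes(), self.default_)
                         for row in X])


class _Linear:
    def __init__(self, loss, **kw):
        self.loss = loss
        self.kw = kw

    def fit(self, X, y, w=None):
        y = np.asarray(y, dtype=float)
        binary = set(np.unique(y)).issubset({0.0, 1.0})
        if self.loss == "log" and binary and len(np.unique(y)) == 2:
            kw = {"C": np.inf, "max_iter": 1000, **self.kw}
            self.model_ = LogisticRegression(**kw)
            self.model_.fit(X, y, sample_weight=w)
            self.is_clf_ = True
        else:
            self.model_ = LinearRegression(**self.kw)
            self.model_.fit(X, y, sample_weight=w)
            self.is_clf_ = False
        return self

    def predict(self, X):
        if self.is_clf_:
            return self.model_.predict_proba(X)[:, 1]
        return self.model_.predict(X)


class _GBT:
    def __init__(self, loss, **kw):
        self.loss = loss
        self.kw = {"max_iter": 100, "max_depth": 3,
                   "early_stopping": False, **kw}

    def fit(self, X, y, w=None):
        y = np.asarray(y, dtype=float)
        binary = set(np.unique(y)).issubset({0.0, 1.0})
        if self.loss == "log" and binary and len(np.unique(y)) == 2:
            self.model_ = HistGradientBoostingClassifier(**self.kw)
            self.model_.fit(X, y, sample_weight=w)
            self.is_clf_ = True
        else:
            self.model_ = HistGradientBoostingRegressor(**self.kw)
            self.model_.fit(X, y, sample_weight=w)
            self.is_clf_ = False
        return self

    def predict(self, X):
        if self.is_clf_:
            return self.model_.predict_proba(X)[:, 1]
        return self.model_.predict(X)


class _KNN:
    def __init__(self, **kw):
        self.kw = kw

    def fit(self, X, y, w=None):  # KNN has no weight support; weights ignored
        k = min(self.kw.pop("n_neighbors", 10) if "n_neighbors" not in self.kw
                else self.kw["n_neighbors"], len(X))
        kw = {k2: v for k2, v in self.kw.items() if k2 != "n_neighbors"}
        self.model_ = KNeighborsRegressor(n_neighbors=max(1, k), **kw)
        self.model_.fit(X, np.asarray(y, dtype=float))
        return self

    def predict(self, X):
        return self.model_.predict(X)


def _make(spec: LearnerSpec):
    if spec.name == "intercept_only":
        return _Intercept()
    if spec.name == "linear_additive":
        return _Linear(spec.loss, **spec.hyperparameters)
    if spec.name == "gradient_boosted_trees":
        return _GBT(spec.loss, **spec.hyperparameters)
    if spec.name == "k_nearest_neighbors":
        return _KNN(**spec.hyperparameters)
    if spec.name == "saturated":
        return _Saturated()
    raise ValueError(spec.name)


def _loss(y, pred, w, kind):
    if kind == "log":
        p = np.clip(pred, _EPS, 1 - _EPS)
        val = -(y * np.log(p) + (1 - y) * np.log1p(-p))
    else:
        val = (y - pred) ** 2
    return float(np.average(val, weights=w))


@dataclass
class SuperLearner:
    specs: list
    weights: np.ndarray
    models: list
    cv_risks: np.ndarray
    ensemble_cv_risk: float
    loss: str

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros(len(X))
        for w, m in zip(self.weights, self.models):
            if w > 0:
                out += w * m.predict(X)
        return out


def fit_superlearner(X, y, learners, v_folds: int = 5, loss: str = "squared",
                     sample_weight=None, seed: int = 0) -> SuperLearner:
    """Fit the convex stacking ensemble.

    ``learners`` is a sequence of registry names or :class:`LearnerSpec`.
    Degenerate (constant) targets short-circuit to an intercept-only
    predictor. A single candidate is refit directly with weight 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    if len(learners) < 1:
        raise ValueError("need at least one learner")
    if v_folds < 2:
        raise ValueError("v_folds must be >= 2")
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    specs = [_as_spec(l, loss) for l in learners]

    if np.ptp(y) == 0.0:  # constant target
        spec = LearnerSpec("intercept_only", loss=loss)
        model = _Intercept().fit(X, y, w)
        return SuperLearner([spec], np.array([1.0]), [model],
                            np.zeros(1), 0.0, loss)

    if len(specs) == 1:
        model = _make(specs[0]).fit(X, y, w)
        risk = _loss(y, model.predict(X), w, loss)
        return SuperLearner(specs, np.array([1.0]), [model],
                            np.array([risk]), risk, loss)

    rng = np.random.default_rng(seed)
    fold = rng.permutation(n) % v_folds
    Z = np.zeros((n, len(specs)))
    for k in range(v_folds):
        tr, te = fold != k, fold == k
        if te.sum() == 0 or tr.sum() == 0:
            continue
        for j, spec in enumerate(specs):
            try:
                m = _make(spec).fit(X[tr], y[tr], w[tr])
                Z[te, j] = m.predict(X[te])
            except Exception:
                Z[te, j] = np.average(y[tr], weights=w[tr])

    cv_risks = np.array([_loss(y, Z[:, j], w, loss) for j in range(len(specs))])

    def objective(alpha):
        return _loss(y, Z @ alpha, w, loss)

    k = len(specs)
    x0 = np.full(k, 1.0 / k)
    res = minimize(objective, x0, method="SLSQP",
                   bounds=[(0.0, 1.0)] * k,
                   constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0}],
                   options={"maxiter": 200, "ftol": 1e-12})
    alpha = np.clip(res.x, 0.0, None) if res.success else None
    if alpha is None or alpha.sum() <= 0:
        alpha = np.zeros(k)
        alpha[int(np.argmin(cv_risks))] = 1.0
    alpha = alpha / alpha.sum()
    # never do worse than the best single candidate
    if objective(alpha) > cv_risks.min():
        alpha = np.zeros(k)
        alpha[int(np.argmin(cv_risks))] = 1.0
    ens_risk = objective(alpha)

    models = [(_make(s).fit(X, y, w) if a > 0 else None)
              for s, a in zip(specs, alpha)]
    models = [m if m is not None else _Intercept().fit(X, y, w) for m in models]
    return SuperLearner(specs, alpha, models, cv_risks, ens_risk, loss)
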