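"""Per-term classifiers over network-row features.

Three models mirror the prediction layer: a linear soft-margin SVM
(C = 100) with maximum-likelihood sigmoid (Platt) calibration of its
margins, an L1-regularized logistic regression, and a 61-tree forest
whose trees are trained on bootstrap samples of both the examples and the
feature space, averaging hard votes.

All three are scikit-learn estimators (``fit(X, y)`` with labels in
{-1, +1}, ``decision_function``, ``predict_proba``) so they compose with
sklearn model selection; the linear solvers themselves are liblinear via
scikit-learn.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_X_y, check_array

from .errors import CalibrationError, ConfigurationError
from .features import FeatureView

DEFAULT_SOLVER_TOL = 1e-6


# ---------------------------------------------------------------------------
# Platt sigmoid calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SigmoidCalibration:
    """p(s) = 1 / (1 + exp(A*s + B)); A < 0 makes p increase with s."""

    A: float
    B: float

    def predict(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        return 1.0 / (1.0 + np.exp(self.A * s + self.B))


def calibrate_sigmoid(scores: Sequence[float], labels: Sequence[int]) -> SigmoidCalibration:
    """Maximum-likelihood sigmoid fit with Platt's smoothed targets.

    Targets are (N+ + 1)/(N+ + 2) for positives and 1/(N- + 2) for
    negatives, which keeps fitted probabilities strictly inside (0, 1)
    even for perfectly separated scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    n_pos = int((y > 0).sum())
    n_neg = int((y <= 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError("both classes required for calibration")
    if np.allclose(s, s[0]):
        raise CalibrationError("degenerate scores: all decision values equal")
    t = np.where(y > 0, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def objective(ab):
        a, b = ab
        z = a * s + b
        # cross-entropy of t against sigma(-z), numerically stable
        nll = np.sum(t * np.logaddexp(0.0, z) + (1.0 - t) * np.logaddexp(0.0, -z))
        p = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
        d = t - p  # dF/dz = t - p with p = sigma(-z)
        return nll, np.array([np.sum(d * s), np.sum(d)])

    res = minimize(objective, x0=np.array([-1.0, 0.0]), jac=True, method="BFGS")
    a, b = res.x
    if a >= 0:
        # monotone fallback along the observed score direction
        a = -1e-6
    return SigmoidCalibration(float(a), float(b))


def _prevalence_calibration(n_pos: int, n_neg: int) -> SigmoidCalibration:
    prev = (n_pos + 1.0) / (n_pos + n_neg + 2.0)
    return SigmoidCalibration(A=-1e-9, B=float(math.log((1 - prev) / prev)))


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _check_two_classes(y: np.ndarray, name: str) -> None:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ConfigurationError(f"{name}: training data contains a single class")


class NetworkSVM(BaseEstimator, ClassifierMixin):
    """Linear soft-margin SVM over network rows with Platt calibration.

    C defaults to 100. Class imbalance (a handful of positives against
    the genome) is handled by inverse-frequency instance weights. The
    calibration sigmoid is fit on cross-validated decision values
    (``calibration_folds``) to avoid optimistic probabilities; when folds
    are infeasible it falls back to training-set values, and to the class
    prevalence when scores are degenerate.
    """

    def __init__(
        self,
        C: float = 100.0,
        tol: float = DEFAULT_SOLVER_TOL,
        class_weight: Optional[str] = "balanced",
        calibration_folds: int = 3,
        max_iter: int = 20000,
        random_state: Optional[int] = 0,
    ):
        self.C = C
        self.tol = tol
        self.class_weight = class_weight
        self.calibration_folds = calibration_folds
        self.max_iter = max_iter
        self.random_state = random_state

    def _svc(self) -> LinearSVC:
        return LinearSVC(
            C=self.C,
            loss="squared_hinge",
            dual=True,  # n_features ~ n_samples; dual coordinate descent is far faster here
            tol=self.tol,
            class_weight=self.class_weight,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        _check_two_classes(y, "NetworkSVM")
        svc = self._svc().fit(X, y)
        self.coef_ = svc.coef_.ravel()
        self.intercept_ = float(svc.intercept_[0])
        self.classes_ = svc.classes_
        self._svc_ = svc
        self.calibration_ = self._calibrate(X, y)
        return self

    def _cv_decision_values(self, X, y) -> Optional[np.ndarray]:
        n_pos = int((y > 0).sum())
        n_neg = int((y <= 0).sum())
        k = min(self.calibration_folds, n_pos, n_neg)
        if k < 2:
            return None
        scores = np.empty(len(y))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=self.random_state)
        for train_idx, test_idx in skf.split(X, y):
            svc = self._svc().fit(X[train_idx], y[train_idx])
            scores[test_idx] = svc.decision_function(X[test_idx])
        return scores

    def _calibrate(self, X, y) -> SigmoidCalibration:
        scores = self._cv_decision_values(X, y)
        if scores is None:
            scores = self._svc_.decision_function(X)
        try:
            return calibrate_sigmoid(scores, y)
        except CalibrationError:
            return _prevalence_calibration(int((y > 0).sum()), int((y <= 0).sum()))

    def decision_function(self, X) -> np.ndarray:
        X = check_array(X)
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.calibration_.predict(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


def train_linear_svm(features: FeatureView, train, C: float = 100.0, **kwargs) -> NetworkSVM:
    X, y, _ = features.design(sorted(train.positives), sorted(train.negatives))
    return NetworkSVM(C=C, **kwargs).fit(X, y)


class L1LogisticNetwork(BaseEstimator, ClassifierMixin):
    """L1-regularized logistic regression (liblinear), objective
    lam * ||w||_1 + sum_i log(1 + exp(-y_i (w.x_i + b))).
    """

    def __init__(
        self,
        lam: float = 1.0,
        tol: float = DEFAULT_SOLVER_TOL,
        class_weight: Optional[str] = "balanced",
        max_iter: int = 5000,
    ):
        self.lam = lam
        self.tol = tol
        self.class_weight = class_weight
        self.max_iter = max_iter

    def fit(self, X, y):
        if self.lam <= 0:
            raise ConfigurationError("lam must be positive")
        X, y = check_X_y(X, y)
        _check_two_classes(y, "L1LogisticNetwork")
        lr = LogisticRegression(
            l1_ratio=1,
            C=1.0 / self.lam,
            solver="liblinear",
            tol=self.tol,
            class_weight=self.class_weight,
            max_iter=self.max_iter,
        ).fit(X, y)
        self._lr_ = lr
        self.coef_ = lr.coef_.ravel()
        self.intercept_ = float(lr.intercept_[0])
        self.classes_ = lr.classes_
        return self

    def decision_function(self, X) -> np.ndarray:
        X = check_array(X)
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        return self._lr_.predict_proba(check_array(X))

    def predict(self, X) -> np.ndarray:
        return self._lr_.predict(check_array(X))

    @property
    def n_nonzero_(self) -> int:
        return int(np.sum(self.coef_ != 0))


def train_l1_logistic(features: FeatureView, train, lam: float = 1.0, **kwargs) -> L1LogisticNetwork:
    X, y, _ = features.design(sorted(train.positives), sorted(train.negatives))
    return L1LogisticNetwork(lam=lam, **kwargs).fit(X, y)


class FeatureBaggedForest(BaseEstimator, ClassifierMixin):
    """Forest of 61 decision trees on bootstrap samples of examples and of
    the feature space (features sampled with replacement, deduplicated),
    predicting the average of hard class votes.

    An odd tree count keeps the averaged vote away from exactly 0.5.
    """

    def __init__(
        self,
        n_trees: int = 61,
        max_depth: Optional[int] = None,
        class_weight: Optional[str] = "balanced",
        random_state: Optional[int] = None,
    ):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        single_class = len(self.classes_) < 2
        rng = check_random_state(self.random_state)
        n, d = X.shape
        self.trees_: List[DecisionTreeClassifier] = []
        self.feature_subsets_: List[np.ndarray] = []
        for _ in range(self.n_trees):
            rows = rng.randint(0, n, size=n)
            feats = np.unique(rng.randint(0, d, size=d))
            self.feature_subsets_.append(feats)
            if single_class:
                self.trees_.append(None)
                continue
            while len(np.unique(y[rows])) < 2:  # resample until both classes present
                rows = rng.randint(0, n, size=n)
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                class_weight=self.class_weight,
                random_state=rng.randint(0, 2**31 - 1),
            )
            tree.fit(X[np.ix_(rows, feats)], y[rows])
            self.trees_.append(tree)
        self._single_class = single_class
        return self

    def vote_fraction(self, X) -> np.ndarray:
        """Fraction of trees voting for the positive (largest) class."""
        X = check_array(X)
        if self._single_class:
            vote = 1.0 if self.classes_[-1] > 0 else 0.0
            return np.full(X.shape[0], vote)
        pos = self.classes_[-1]
        votes = np.zeros(X.shape[0])
        for tree, feats in zip(self.trees_, self.feature_subsets_):
            votes += tree.predict(X[:, feats]) == pos
        return votes / self.n_trees

    decision_function = vote_fraction

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.vote_fraction(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return np.where(self.vote_fraction(X) >= 0.5, self.classes_[-1], self.classes_[0])


def train_forest(
    features: FeatureView, train, n_trees: int = 61, seed: Optional[int] = None, **kwargs
) -> FeatureBaggedForest:
    X, y, _ = features.design(sorted(train.positives), sorted(train.negatives))
    return FeatureBaggedForest(n_trees=n_trees, random_state=seed, **kwargs).fit(X, y)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def rank_genes(
    model,
    features: FeatureView,
    universe: Iterable[str],
    training_genes: Iterable[str] = (),
) -> pd.DataFrame:
    """Score every universe gene and rank descending (ties lexicographic).

    Training genes are flagged via ``in_training`` rather than removed.
    Columns: gene, rank, raw_score, probability, in_training.
    """
    genes = sorted(universe)
    X = features.rows(genes)
    raw = np.asarray(model.decision_function(X), dtype=float)
    if hasattr(model, "predict_proba"):
        prob = np.asarray(model.predict_proba(X))[:, 1]
    else:  # pragma: no cover - all bundled models expose predict_proba
        prob = raw
    training = set(training_genes)
    df = pd.DataFrame(
        {
            "gene": genes,
            "raw_score": raw,
            "probability": prob,
            "in_training": [int(g in training) for g in genes],
        }
    )
    df = df.sort_values(
        ["raw_score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df[["gene", "rank", "raw_score", "probability", "in_training"]]
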