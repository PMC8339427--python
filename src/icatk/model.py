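"""Impairment classifier: SGD-trained logistic regression on session features.

The model maps four features — accuracy (%), speed, ICA Index and age — to a
probability of cognitive impairment via binary logistic regression fitted with
stochastic gradient descent.  Features are standardized with statistics of the
training data only.  A probability threshold of 0.5 (inclusive on the
impaired side) converts the probability to a label, and the probability is
presented to users as ``ICA Score = (1 - probability) * 100``.

Evaluation utilities implement leave-one-out cross-validation (one held-out
participant per fold, per-fold standardization), cross-cohort transfer
(train on one cohort, test on the other) and learning curves over training-set
size with repeated random subsampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import SGDClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import metrics as _metrics
from .scoring import ica_score

__all__ = [
    "FEATURE_NAMES",
    "IMPAIRED_DIAGNOSES",
    "ImpairmentClassifier",
    "Prediction",
    "LearningCurveResult",
    "feature_matrix",
    "impairment_labels",
    "loocv",
    "cross_cohort_evaluate",
    "learning_curve",
    "save_model",
    "load_model",
]

FEATURE_NAMES = ("accuracy_pct", "speed", "ica_index", "age")
IMPAIRED_DIAGNOSES = frozenset({"mci", "mild_ad"})
DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class Prediction:
    """One participant's model output."""

    ai_probability: float
    predicted_label: str
    ica_score: float

    def __post_init__(self) -> None:
        if not 0 <= self.ai_probability <= 1:
            raise ValueError("ai_probability must be in [0, 1]")


@dataclass(frozen=True)
class LearningCurveResult:
    """Mean test AUC (with 95% CI) per training-set size."""

    sizes: tuple[int, ...]
    mean_auc: tuple[float, ...]
    ci_low: tuple[float, ...]
    ci_high: tuple[float, ...]
    n_repetitions: int

    def __post_init__(self) -> None:
        if list(self.sizes) != sorted(set(self.sizes)) or (self.sizes and self.sizes[0] < 3):
            raise ValueError("sizes must be strictly increasing and >= 3")
        for lo, m, hi in zip(self.ci_low, self.mean_auc, self.ci_high):
            if not (lo <= m + 1e-12 and m <= hi + 1e-12):
                raise ValueError("CI bounds must bracket the mean")


class ImpairmentClassifier(ClassifierMixin, BaseEstimator):
    """Logistic regression fitted by stochastic gradient descent.

    Parameters mirror :class:`sklearn.linear_model.SGDClassifier` with
    logistic loss; feature standardization (fitted on training data only) is
    built in, so the estimator can be used directly in cross-validation
    without leaking test statistics.

    Parameters
    ----------
    alpha : L2 regularization strength.
    max_iter : maximum SGD epochs.
    tol : stopping tolerance.
    learning_rate, eta0 : SGD learning-rate schedule.
    average : use iterate averaging (ASGD), which stabilizes the fit at
        small sample sizes.
    threshold : probability at or above which the impaired label is predicted.
    random_state : seed for the SGD shuffling; fixes the fit exactly.

    Attributes
    ----------
    classes_ : array of the two class labels (sorted; the second is treated
        as the impaired/positive class).
    coef_, intercept_ : weights on the standardized features.
    standardization_mean_, standardization_scale_ : per-feature training
        statistics.
    """

    def __init__(
        self,
        alpha: float = 1e-4,
        max_iter: int = 1000,
        tol: float = 1e-4,
        learning_rate: str = "adaptive",
        eta0: float = 0.01,
        average: bool = True,
        threshold: float = DEFAULT_THRESHOLD,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol
        self.learning_rate = learning_rate
        self.eta0 = eta0
        self.average = average
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(
                f"training data must contain exactly two classes, got {classes.tolist()}"
            )
        self.scaler_ = StandardScaler().fit(X)
        if np.any(self.scaler_.scale_ <= 0):
            raise ValueError("a feature is constant in the training data")
        self.sgd_ = SGDClassifier(
            loss="log_loss",
            penalty="l2",
            alpha=self.alpha,
            max_iter=self.max_iter,
            tol=self.tol,
            learning_rate=self.learning_rate,
            eta0=self.eta0,
            average=self.average,
            random_state=self.random_state,
        ).fit(self.scaler_.transform(X), y)
        self.classes_ = self.sgd_.classes_
        self.coef_ = self.sgd_.coef_
        self.intercept_ = self.sgd_.intercept_
        self.standardization_mean_ = self.scaler_.mean_
        self.standardization_scale_ = self.scaler_.scale_
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "sgd_")
        X = check_array(X, dtype=float)
        return self.sgd_.decision_function(self.scaler_.transform(X))

    def predict_proba(self, X):
        check_is_fitted(self, "sgd_")
        X = check_array(X, dtype=float)
        return self.sgd_.predict_proba(self.scaler_.transform(X))

    def predict(self, X):
        proba = self.predict_proba(X)[:, 1]
        return np.where(proba >= self.threshold, self.classes_[1], self.classes_[0])

    def predict_one(self, features) -> Prediction:
        """Full model output (probability, label, score) for one participant."""
        proba = float(self.predict_proba(np.atleast_2d(features))[0, 1])
        label = self.classes_[1] if proba >= self.threshold else self.classes_[0]
        return Prediction(ai_probability=proba, predicted_label=str(label), ica_score=ica_score(proba))


def feature_matrix(frame: pd.DataFrame) -> np.ndarray:
    """Extract the (accuracy, speed, index, age) feature matrix from a table."""
    missing = [c for c in FEATURE_NAMES if c not in frame.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    return frame.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)


def impairment_labels(diagnoses: Sequence[str]) -> np.ndarray:
    """Collapse detailed diagnoses to the binary healthy/impaired label."""
    return np.array(
        ["impaired" if d in IMPAIRED_DIAGNOSES else "healthy" for d in diagnoses]
    )


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lexicographic row order, making seeded SGD fits input-order invariant."""
    keys = tuple(X[:, j] for j in range(X.shape[1] - 1, -1, -1))
    return np.lexsort((np.asarray(y, dtype=str),) + keys)


def loocv(
    X,
    y,
    estimator: ImpairmentClassifier | None = None,
    rng_seed: int = 0,
) -> np.ndarray:
    """Leave-one-out cross-validated impairment probabilities.

    Each fold refits the full estimator (including standardization) on the
    other N-1 examples and predicts the held-out one.  Training rows are put
    in a canonical order before each fit, so the per-example probabilities do
    not depend on the order the examples are supplied in.  Folds whose
    training part loses a class entirely are skipped with a NaN probability.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have the same length")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("leave-one-out requires at least two examples of each class")
    base = estimator if estimator is not None else ImpairmentClassifier(random_state=rng_seed)
    probs = np.full(X.shape[0], np.nan)
    for i in range(X.shape[0]):
        mask = np.ones(X.shape[0], dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], y[mask]
        if np.unique(y_tr).size < 2:
            import warnings

            warnings.warn(f"fold {i}: a class is absent from the training part; skipped")
            continue
        order = _canonical_order(X_tr, y_tr)
        est = clone(base).fit(X_tr[order], y_tr[order])
        probs[i] = est.predict_proba(X[i : i + 1])[0, 1]
    return probs


def cross_cohort_evaluate(
    X_train,
    y_train,
    X_test,
    y_test,
    estimator: ImpairmentClassifier | None = None,
    rng_seed: int = 0,
) -> dict:
    """Train on one cohort, evaluate on the other.

    Returns AUC (on the continuous probability), sensitivity and specificity
    at the probability threshold, with sample sizes.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    if X_test.shape[0] == 0:
        raise ValueError("test cohort is empty")
    est = (estimator if estimator is not None else ImpairmentClassifier(random_state=rng_seed))
    est = clone(est).fit(X_train, y_train)
    proba = est.predict_proba(X_test)[:, 1]
    pred = est.predict(X_test)
    auc = _metrics.roc_auc(proba, y_test, positive_label=est.classes_[1])
    bm = _metrics.sensitivity_specificity(pred, y_test, positive_label=est.classes_[1])
    return {
        "auc": auc,
        "sensitivity_pct": bm.sensitivity_pct,
        "specificity_pct": bm.specificity_pct,
        "n_train": int(X_train.shape[0]),
        "n_test": int(X_test.shape[0]),
    }


def learning_curve(
    X_train,
    y_train,
    X_test,
    y_test,
    sizes: Sequence[int] | None = None,
    n_repetitions: int = 20,
    rng_seed: int = 0,
    estimator: ImpairmentClassifier | None = None,
    max_redraws: int = 100,
) -> LearningCurveResult:
    """Test AUC as a function of training-set size.

    For each size, ``n_repetitions`` random training subsets are drawn
    (redrawn up to ``max_redraws`` times until both classes are present),
    fitted, and evaluated on the full test cohort.  The 95% CI is the normal
    approximation over repetitions (width zero when the subset is the full
    training set, since every repetition is then identical).
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    n = X_train.shape[0]
    if sizes is None:
        grid = [3, 5, 10, 20, 40, 80, 160]
        sizes = sorted({s for s in grid if s < n} | {n})
    sizes = list(sizes)
    if any(s < 3 for s in sizes):
        raise ValueError("training sizes must be >= 3")
    if any(s > n for s in sizes):
        raise ValueError(f"training sizes must be <= {n}")
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    rng = np.random.default_rng(rng_seed)
    base = estimator if estimator is not None else ImpairmentClassifier(random_state=rng_seed)
    positive = np.unique(y_train)[1]

    means, los, his = [], [], []
    for size in sizes:
        aucs = []
        for _rep in range(n_repetitions):
            for _ in range(max_redraws):
                idx = rng.choice(n, size=size, replace=False)
                if np.unique(y_train[idx]).size == 2:
                    break
            else:
                import warnings

                warnings.warn(f"size {size}: no two-class subset found; repetition skipped")
                continue
            est = clone(base).fit(X_train[idx], y_train[idx])
            proba = est.predict_proba(X_test)[:, 1]
            aucs.append(_metrics.roc_auc(proba, y_test, positive_label=positive))
        aucs = np.array(aucs)
        m = float(aucs.mean())
        half = 1.959964 * float(aucs.std(ddof=1) / np.sqrt(aucs.size)) if aucs.size > 1 else 0.0
        means.append(m)
        los.append(m - half)
        his.append(m + half)
    return LearningCurveResult(
        sizes=tuple(int(s) for s in sizes),
        mean_auc=tuple(means),
        ci_low=tuple(los),
        ci_high=tuple(his),
        n_repetitions=n_repetitions,
    )


def save_model(est: ImpairmentClassifier, path: str | Path) -> None:
    """Persist a fitted model as JSON (weights, standardization, parameters)."""
    check_is_fitted(est, "sgd_")
    payload = {
        "classes": [str(c) for c in est.classes_],
        "coef": est.coef_.tolist(),
        "intercept": est.intercept_.tolist(),
        "standardization_mean": est.standardization_mean_.tolist(),
        "standardization_scale": est.standardization_scale_.tolist(),
        "params": est.get_params(),
        "feature_names": list(FEATURE_NAMES),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path: str | Path) -> ImpairmentClassifier:
    """Rebuild a fitted model from its JSON persistence."""
    payload = json.loads(Path(path).read_text())
    est = ImpairmentClassifier(**payload["params"])
    est.scaler_ = StandardScaler()
    est.scaler_.mean_ = np.array(payload["standardization_mean"])
    est.scaler_.scale_ = np.array(payload["standardization_scale"])
    est.scaler_.var_ = est.scaler_.scale_ ** 2
    est.scaler_.n_features_in_ = len(payload["standardization_mean"])
    est.sgd_ = SGDClassifier(loss="log_loss")
    est.sgd_.classes_ = np.array(payload["classes"])
    est.sgd_.coef_ = np.array(payload["coef"])
    est.sgd_.intercept_ = np.array(payload["intercept"])
    est.classes_ = est.sgd_.classes_
    est.coef_ = est.sgd_.coef_
    est.intercept_ = est.sgd_.intercept_
    est.standardization_mean_ = est.scaler_.mean_
    est.standardization_scale_ = est.scaler_.scale_
    est.n_features_in_ = est.scaler_.n_features_in_
    return est
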