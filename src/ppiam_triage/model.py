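"""Gradient-boosted triage classifier, calibration, and evaluation.

The classifier contract is regularized gradient-boosted decision trees
(XGBoost) over the assembled feature vectors, tuned by grid search with
stratified 10-fold cross-validation on average precision, then
calibrated with Platt scaling (a logistic regression fitted to predict
labels from out-of-fold scores) and thresholded at a configurable
cutoff (default 0.35): a document is predicted relevant iff its
calibrated probability is strictly greater than the cutoff.

Evaluation metrics: precision = TP/(TP+FP), recall = TP/(TP+FN), F1 the
harmonic mean, and average precision (AvPr) — the area under the
precision-recall curve, computed as the mean of precision at the ranks
of the true positives under a stable descending sort of the scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from xgboost import XGBClassifier

DEFAULT_CUTOFF = 0.35

#: default hyperparameter grid (config-exposed; no canonical grid exists)
DEFAULT_GRID = {
    "max_depth": [3, 5, 7],
    "learning_rate": [0.05, 0.1],
    "n_estimators": [200, 500],
    "reg_lambda": [1, 5],
}


# ---------------------------------------------------------------------------
# metrics


def precision_recall_f1(y_true: Sequence[int], y_pred: Sequence[int],
                        ) -> tuple[float, float, float]:
    """Precision, recall and F1 with the 0/0 -> 0 convention."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must be aligned")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = f1_score(precision, recall)
    return precision, recall, f1


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 / (1.0 / precision + 1.0 / recall)


def average_precision(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Mean of precision at the ranks of true positives.

    Documents are ranked by descending score with a stable sort, so tied
    scores keep their input order. Equals the step-wise area under the
    precision-recall curve.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("labels and scores must be aligned")
    n_pos = int(np.sum(y_true == 1))
    if n_pos == 0:
        raise ValueError("average precision needs at least one positive label")
    order = np.argsort(-scores, kind="stable")
    ranked = y_true[order]
    hits = 0
    total = 0.0
    for rank, lab in enumerate(ranked, start=1):
        if lab == 1:
            hits += 1
            total += hits / rank
    return total / n_pos


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    average_precision: float
    cutoff_curve: Optional[list[dict]] = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1), encoding="utf-8")
        return path


def evaluate(y_true: Sequence[int], y_pred: Sequence[int],
             probabilities: Sequence[float],
             cutoff_grid: Optional[Sequence[float]] = None) -> EvalReport:
    """All four metrics (and optionally the per-cutoff curve)."""
    p, r, f1 = precision_recall_f1(y_true, y_pred)
    avpr = average_precision(y_true, probabilities)
    curve = None
    if cutoff_grid is not None:
        curve = cutoff_curve(y_true, probabilities, cutoff_grid)
    return EvalReport(precision=p, recall=r, f1=f1, average_precision=avpr,
                      cutoff_curve=curve)


def cutoff_curve(y_true: Sequence[int], probabilities: Sequence[float],
                 cutoff_grid: Sequence[float]) -> list[dict]:
    """Precision/recall/F1 at each cutoff under the strict > rule."""
    y_true = np.asarray(y_true)
    probs = np.asarray(probabilities, dtype=float)
    out = []
    for c in cutoff_grid:
        pred = (probs > c).astype(int)
        p, r, f1 = precision_recall_f1(y_true, pred)
        out.append({"cutoff": float(c), "precision": p, "recall": r, "f1": f1})
    return out


# ---------------------------------------------------------------------------
# Platt scaling


class PlattCalibrator:
    """Monotone logistic map from raw scores to calibrated probabilities."""

    def __init__(self) -> None:
        self.lr_: Optional[LogisticRegression] = None
        self.constant_: Optional[float] = None

    def fit(self, scores: Sequence[float], labels: Sequence[int],
            ) -> "PlattCalibrator":
        scores = np.asarray(scores, dtype=float).reshape(-1, 1)
        labels = np.asarray(labels)
        if scores.shape[0] != labels.shape[0]:
            raise ValueError("scores and labels must be aligned")
        if len(set(labels.tolist())) < 2:
            raise ValueError("calibration needs both classes present")
        if np.ptp(scores) == 0:
            warnings.warn("degenerate scores (all equal); calibration is flat")
            self.constant_ = float(np.mean(labels))
            return self
        lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
        lr.fit(scores, labels)
        if lr.coef_[0, 0] < 0:  # enforce a non-decreasing map
            warnings.warn("anti-monotone calibration fit; flattening")
            self.constant_ = float(np.mean(labels))
            return self
        self.lr_ = lr
        return self

    def predict(self, scores: Sequence[float]) -> np.ndarray:
        scores = np.asarray(scores, dtype=float).reshape(-1, 1)
        if self.lr_ is None:
            if self.constant_ is None:
                raise ValueError("calibrator is not fitted")
            return np.full(scores.shape[0], self.constant_)
        return self.lr_.predict_proba(scores)[:, 1]


def platt_calibrate(scores: Sequence[float], labels: Sequence[int],
                    ) -> PlattCalibrator:
    return PlattCalibrator().fit(scores, labels)


# ---------------------------------------------------------------------------
# the classifier


class TriageClassifier(BaseEstimator, ClassifierMixin):
    """Calibrated gradient-boosted triage classifier.

    Parameters
    ----------
    param_grid
        Hyperparameter grid for XGBoost; a single-point grid skips the
        grid search. None uses the packaged default grid.
    cv
        Folds for the tuning cross-validation (stratified).
    calibration_cv
        Folds used to produce out-of-fold scores for Platt scaling.
    cutoff
        Decision threshold; predict 1 iff probability > cutoff (strict).
    calibrate
        Disable to use raw booster probabilities.
    random_state
        Seed for fold assignment and the booster.

    Attributes (after fit)
    ----------------------
    best_params_ : selected hyperparameters
    cv_average_precision_ : mean CV average precision of the selection
        (nan for a single-point grid)
    booster_ : the fitted XGBClassifier
    calibrator_ : fitted PlattCalibrator (or None)
    """

    def __init__(self, param_grid: Optional[dict] = None, cv: int = 10,
                 calibration_cv: int = 5, cutoff: float = DEFAULT_CUTOFF,
                 calibrate: bool = True, random_state: int = 42,
                 n_jobs: int = 1):
        self.param_grid = param_grid
        self.cv = cv
        self.calibration_cv = calibration_cv
        self.cutoff = cutoff
        self.calibrate = calibrate
        self.random_state = random_state
        self.n_jobs = n_jobs

    def _new_booster(self, **params) -> XGBClassifier:
        return XGBClassifier(
            random_state=self.random_state, n_jobs=self.n_jobs,
            eval_metric="logloss", tree_method="hist", **params)

    def fit(self, X, y) -> "TriageClassifier":
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must be aligned")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training labels contain a single class")
        if not (0 < self.cutoff < 1):
            raise ValueError("cutoff must lie in (0, 1)")
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        grid = self.param_grid if self.param_grid is not None else DEFAULT_GRID
        if not grid:
            raise ValueError("param_grid must be non-empty")
        n_combos = int(np.prod([len(v) for v in grid.values()])) if grid else 0
        skf = StratifiedKFold(n_splits=self.cv, shuffle=True,
                              random_state=self.random_state)
        if n_combos == 1:
            self.best_params_ = {k: v[0] for k, v in grid.items()}
            self.cv_average_precision_ = float("nan")
        else:
            search = GridSearchCV(self._new_booster(), grid,
                                  scoring="average_precision", cv=skf,
                                  n_jobs=self.n_jobs, refit=False)
            search.fit(X, y)
            self.best_params_ = search.best_params_
            self.cv_average_precision_ = float(search.best_score_)
        self.booster_ = self._new_booster(**self.best_params_)
        self.booster_.fit(X, y)
        self.calibrator_ = None
        if self.calibrate:
            cal_skf = StratifiedKFold(n_splits=self.calibration_cv,
                                      shuffle=True,
                                      random_state=self.random_state)
            oof = cross_val_predict(self._new_booster(**self.best_params_),
                                    X, y, cv=cal_skf, method="predict_proba",
                                    n_jobs=self.n_jobs)[:, 1]
            self.calibrator_ = PlattCalibrator().fit(oof, y)
        return self

    def _check_fitted_dims(self, X) -> None:
        if not hasattr(self, "booster_"):
            raise ValueError("TriageClassifier is not fitted")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension mismatch: fitted with "
                f"{self.n_features_in_}, got {X.shape[1]}")

    def predict_proba(self, X) -> np.ndarray:
        """Calibrated class probabilities, shape (n, 2)."""
        self._check_fitted_dims(X)
        raw = self.booster_.predict_proba(X)[:, 1]
        p1 = self.calibrator_.predict(raw) if self.calibrator_ is not None else raw
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        """1 iff calibrated probability is strictly greater than cutoff."""
        return (self.predict_proba(X)[:, 1] > self.cutoff).astype(int)

    def predict_with_scores(self, X) -> tuple[np.ndarray, np.ndarray]:
        """(probabilities, labels) under the strict cutoff rule."""
        p = self.predict_proba(X)[:, 1]
        return p, (p > self.cutoff).astype(int)


def grid_search_fit(X, y, grid: Optional[dict] = None, k: int = 10,
                    seed: int = 42, cutoff: float = DEFAULT_CUTOFF,
                    ) -> TriageClassifier:
    """Thin wrapper: tune, refit, calibrate; returns the fitted model."""
    clf = TriageClassifier(param_grid=grid, cv=k, random_state=seed,
                           cutoff=cutoff)
    return clf.fit(X, y)
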