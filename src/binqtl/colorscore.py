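"""Fruit color comprehensive score (FCS) from CIELAB measurements.

An ordinary least-squares model ``FCS = b0 + b1*L + b2*a + b3*b`` maps the
colorimeter triplet (L, a*, b*) to a continuous yellow-to-orange score
anchored on a 10-level color-card grading.  Training follows a 70/30
train/test split with 5-fold cross-validation on the training subset, and
the final model is refit on the full training subset.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import KFold, train_test_split

_FEATURES = ["L", "a", "b"]


@dataclasses.dataclass
class ColorModel:
    """Fitted FCS model: intercept, three coefficients, and metrics."""

    b0: float
    b1: float
    b2: float
    b3: float
    n_train: int = 0
    split: float = 0.70
    seed: int | None = None
    cv_metrics: dict = dataclasses.field(default_factory=dict)
    test_metrics: dict = dataclasses.field(default_factory=dict)
    grade_range: tuple[float, float] | None = None

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.b0, self.b1, self.b2, self.b3])

    def predict(self, L, a, b) -> np.ndarray | float:
        return predict_fcs(self, L, a, b)

    def to_json(self, path: str) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "ColorModel":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("grade_range") is not None:
            d["grade_range"] = tuple(d["grade_range"])
        return cls(**d)


class FCSRegressor(RegressorMixin, BaseEstimator):
    """sklearn estimator for the linear FCS model.

    Thin wrapper over :class:`~sklearn.linear_model.LinearRegression` that
    checks the design for rank deficiency and exposes the intercept and
    coefficients as ``b0_`` .. ``b3_``.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FCSRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n, 3): columns L, a*, b*")
        design = np.column_stack([np.ones(len(X)), X])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("rank-deficient design (constant or collinear color channel)")
        self.model_ = LinearRegression().fit(X, y)
        self.b0_ = float(self.model_.intercept_)
        self.b1_, self.b2_, self.b3_ = (float(c) for c in self.model_.coef_)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.model_.predict(X)


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    return {
        "r2": float(r2_score(y_true, y_pred)),
        "mae": float(mean_absolute_error(y_true, y_pred)),
        "rmse": float(np.sqrt(mean_squared_error(y_true, y_pred))),
    }


def cross_validate_fcs(training: pd.DataFrame, k: int = 5, seed: int | None = 0) -> dict[str, float]:
    """k-fold CV of the FCS model; mean and sd of R2, MAE, RMSE over folds.

    Each record appears in exactly one validation fold.  A fold whose
    response has zero variance yields an undefined R2 for that fold and is
    flagged with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(training) < k:
        raise ValueError("need at least k rows")
    X = training[_FEATURES].to_numpy(dtype=float)
    y = training["grade"].to_numpy(dtype=float)
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = {"r2": [], "mae": [], "rmse": []}
    for train_idx, val_idx in folds.split(X):
        est = FCSRegressor().fit(X[train_idx], y[train_idx])
        pred = est.predict(X[val_idx])
        if np.var(y[val_idx]) == 0:
            warnings.warn("validation fold has zero response variance; R2 undefined", stacklevel=2)
            per_fold["r2"].append(np.nan)
        else:
            per_fold["r2"].append(r2_score(y[val_idx], pred))
        per_fold["mae"].append(mean_absolute_error(y[val_idx], pred))
        per_fold["rmse"].append(np.sqrt(mean_squared_error(y[val_idx], pred)))
    out = {}
    for key, vals in per_fold.items():
        arr = np.asarray(vals, dtype=float)
        out[f"{key}_mean"] = float(np.nanmean(arr))
        out[f"{key}_sd"] = float(np.nanstd(arr, ddof=1))
    return out


def fit_fcs(
    table: pd.DataFrame,
    split: float = 0.70,
    seed: int | None = 0,
    k: int = 5,
    stratify_by_grade: bool = False,
) -> ColorModel:
    """Full training protocol: split, cross-validate, refit, evaluate held-out.

    ``table`` needs columns L, a, b, grade (>= 10 rows).  The split is
    uniform random with the recorded seed; set ``stratify_by_grade`` for a
    grade-stratified split (grades are banded, so stratification is offered
    as an option).
    """
    for col in _FEATURES + ["grade"]:
        if col not in table.columns:
            raise ValueError(f"training table needs column {col!r}")
    if len(table) < 10:
        raise ValueError("need at least 10 training rows")
    strat = table["grade"] if stratify_by_grade else None
    train, test = train_test_split(table, train_size=split, random_state=seed, stratify=strat)
    cv = cross_validate_fcs(train, k=k, seed=seed)
    est = FCSRegressor().fit(train[_FEATURES].to_numpy(float), train["grade"].to_numpy(float))
    pred = est.predict(test[_FEATURES].to_numpy(float))
    return ColorModel(
        b0=est.b0_,
        b1=est.b1_,
        b2=est.b2_,
        b3=est.b3_,
        n_train=len(train),
        split=split,
        seed=seed,
        cv_metrics=cv,
        test_metrics=_metrics(test["grade"].to_numpy(float), pred),
        grade_range=(float(train["grade"].min()), float(train["grade"].max())),
    )


def predict_fcs(model: ColorModel, L, a, b) -> np.ndarray | float:
    """Apply the linear formula; extrapolation outside the training grade
    range is permitted but flagged with a warning."""
    L_arr, a_arr, b_arr = (np.asarray(v, dtype=float) for v in (L, a, b))
    if not (np.all(np.isfinite(L_arr)) and np.all(np.isfinite(a_arr)) and np.all(np.isfinite(b_arr))):
        raise ValueError("non-finite color input")
    score = model.b0 + model.b1 * L_arr + model.b2 * a_arr + model.b3 * b_arr
    if model.grade_range is not None:
        lo, hi = model.grade_range
        if np.any(score < lo) or np.any(score > hi):
            warnings.warn("prediction outside the training grade range (extrapolation)", stacklevel=2)
    return float(score) if np.isscalar(L) and np.isscalar(a) and np.isscalar(b) else score
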