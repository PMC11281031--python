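"""Descriptor-only baseline learners (scikit-learn behind the scenes).

Classification: random forest, bagged decision trees, AdaBoost.
Regression: random forest, SVR, gradient boosting, kernel ridge, decision
tree with AdaBoost, and k-neighbors — the six that join the HNN in the
seven-model consensus. Scale-sensitive learners (SVR, kernel ridge,
k-neighbors) are wrapped with a training-fold z-score; tree learners consume
raw descriptors.
"""

from __future__ import annotations

from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    AdaBoostRegressor,
    BaggingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.kernel_ridge import KernelRidge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from mixtox.models.base import PredictionSet, Task, labels_from_scores

__all__ = [
    "CLASSIFIER_NAMES",
    "REGRESSOR_NAMES",
    "train_baselines",
    "predict_baseline",
    "save_baselines",
    "load_baselines",
]

CLASSIFIER_NAMES = ("rf", "bagging", "adaboost")
REGRESSOR_NAMES = ("rf", "svr", "gb", "kr", "dt", "kn")


def _make_classifiers(seed: int) -> dict:
    return {
        "rf": RandomForestClassifier(n_estimators=100, random_state=seed),
        "bagging": BaggingClassifier(n_estimators=50, random_state=seed),
        "adaboost": AdaBoostClassifier(n_estimators=100, random_state=seed),
    }


def _make_regressors(seed: int) -> dict:
    return {
        "rf": RandomForestRegressor(n_estimators=100, random_state=seed),
        "svr": make_pipeline(StandardScaler(), SVR()),
        "gb": GradientBoostingRegressor(random_state=seed),
        "kr": make_pipeline(StandardScaler(), KernelRidge(alpha=1.0)),
        "dt": AdaBoostRegressor(
            DecisionTreeRegressor(max_depth=4, random_state=seed),
            n_estimators=50, random_state=seed,
        ),
        "kn": make_pipeline(StandardScaler(), KNeighborsRegressor()),
    }


def train_baselines(task: Task | str, X_desc, y, seed: int = 0) -> dict:
    """Fit the task's baseline suite on the descriptor matrix.

    Returns a name -> fitted-model dict ({rf, bagging, adaboost} for
    classification, {rf, svr, gb, kr, dt, kn} for regression).
    """
    task = Task(task)
    X = np.asarray(X_desc, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("descriptors contain non-finite values; impute first")
    models = (
        _make_regressors(seed) if task is Task.REGRESSION
        else _make_classifiers(seed)
    )
    for model in models.values():
        model.fit(X, y)
    return models


def predict_baseline(model, task: Task | str, X_desc, mixture_ids=None) -> PredictionSet:
    """Wrap a fitted baseline's predictions as a :class:`PredictionSet`."""
    task = Task(task)
    X = np.asarray(X_desc, dtype=float)
    if mixture_ids is None:
        mixture_ids = np.arange(X.shape[0])
    if task is Task.REGRESSION:
        scores = model.predict(X)
    else:
        proba = model.predict_proba(X)
        if task is Task.BINARY:
            classes = list(model.classes_)
            scores = proba[:, classes.index(1)] if 1 in classes else np.zeros(len(X))
        else:
            # map class probabilities onto the fixed 0..4 grid
            scores = np.zeros((X.shape[0], 5))
            for j, cls in enumerate(model.classes_):
                scores[:, int(cls)] = proba[:, j]
            scores = scores / scores.sum(axis=1, keepdims=True)
    return PredictionSet(
        mixture_ids=np.asarray(mixture_ids), task=task,
        scores=scores, labels=labels_from_scores(task, scores),
    )


def save_baselines(models: dict, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, model in models.items():
        joblib.dump(model, d / f"{name}.joblib")


def load_baselines(directory) -> dict:
    d = Path(directory)
    return {p.stem: joblib.load(p) for p in sorted(d.glob("*.joblib"))}
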