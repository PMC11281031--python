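"""Splitting protocols, metrics, and prediction-vs-experiment agreement.

Protocols: repeated random 20% hold-out (30 iterations by default, each
reseeded from the base seed), stratified k-fold, and compound-out splits in
which every test mixture contains at least one held-out chemical. Metrics
follow the standard confusion-matrix definitions with a rank-based
(Mann-Whitney) AUC; multiclass metrics micro-average pooled one-vs-rest
binary decisions.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SplitScheme",
    "MetricsReport",
    "RegressionReport",
    "holdout_indices",
    "stratified_kfold",
    "compound_out_split",
    "classification_metrics",
    "micro_average",
    "regression_metrics",
    "agreement_with_experiment",
    "aggregate_reports",
    "load_table2_fixture",
]


class SplitScheme(str, enum.Enum):
    RANDOM_HOLDOUT = "random_holdout"
    STRATIFIED_KFOLD = "stratified_kfold"
    COMPOUND_OUT = "compound_out"


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    auc: float | None
    n: int
    confusion: tuple[int, int, int, int] = (0, 0, 0, 0)  # TP, FP, TN, FN


@dataclass
class RegressionReport:
    r2: float | None
    mse: float
    mae: float
    n: int


def holdout_indices(
    n: int, seed: int, iteration: int = 0, test_fraction: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test index split; floor(test_fraction * n) test items.

    Each iteration mixes its index into the base seed so the 30-iteration
    protocol draws independent, reproducible splits.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0,1), got {test_fraction}")
    n_test = int(math.floor(test_fraction * n))
    if n_test == 0 or n_test == n:
        raise ValueError(f"degenerate split: n={n}, test_fraction={test_fraction}")
    rng = np.random.default_rng((seed, iteration))
    perm = rng.permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Per-item fold assignment (0..k-1) preserving class proportions."""
    y = np.asarray(labels)
    if k > y.size:
        raise ValueError(f"k={k} exceeds n={y.size}")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size == 1:
        warnings.warn("single-class labels; folds are plain partitions",
                      stacklevel=2)
    elif counts.min() < k:
        warnings.warn(
            f"some class has fewer than k={k} members; folds will be uneven",
            stacklevel=2,
        )
    folds = np.empty(y.size, dtype=int)
    if classes.size == 1:
        rng = np.random.default_rng(seed)
        folds[rng.permutation(y.size)] = np.arange(y.size) % k
        return folds
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(y.size), y)):
        folds[test_idx] = f
    return folds


def compound_out_split(
    mixtures: list[tuple[str, str]],
    held_out_chemicals,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of (train, test) mixtures for a compound-out protocol.

    A mixture is a test item iff it contains at least one held-out chemical,
    so no training mixture touches the held-out set.
    """
    held = set(held_out_chemicals)
    if not held:
        raise ValueError("held_out_chemicals is empty")
    test = [i for i, (a, b) in enumerate(mixtures) if a in held or b in held]
    train = [i for i in range(len(mixtures)) if i not in set(test)]
    if not test:
        raise ValueError(
            "no mixture contains a held-out chemical (empty test set)"
        )
    if not train:
        raise ValueError("every mixture touches a held-out chemical (empty train set)")
    return np.asarray(train), np.asarray(test)


def classification_metrics(labels, predicted, scores=None) -> MetricsReport:
    """Accuracy/sensitivity/specificity/precision and rank-based AUC.

    AUC is the Mann-Whitney probability that a positive outranks a negative,
    ties counted 0.5; it is undefined (None, with a warning) when only one
    class is present or no scores are given.
    """
    y = np.asarray(labels).astype(int)
    yhat = np.asarray(predicted).astype(int)
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("labels and predictions must be non-empty and aligned")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    n = y.size

    def _safe(num, den):
        return float(num / den) if den > 0 else float("nan")

    auc = None
    if scores is not None:
        s = np.asarray(scores, dtype=float)
        if np.unique(y).size < 2:
            warnings.warn("AUC undefined with a single class", stacklevel=2)
        else:
            auc = float(roc_auc_score(y, s))
    return MetricsReport(
        accuracy=float((tp + tn) / n),
        sensitivity=_safe(tp, tp + fn),
        specificity=_safe(tn, tn + fp),
        precision=_safe(tp, tp + fp),
        auc=auc,
        n=n,
        confusion=(tp, fp, tn, fn),
    )


def micro_average(labels, predicted, scores=None) -> MetricsReport:
    """Micro-averaged one-vs-rest metrics for multiclass predictions.

    Every (item, class) pair becomes one pooled binary decision; binary
    metrics are then computed on the pooled table. ``scores`` may be an
    (n, n_classes) probability matrix for the micro AUC.
    """
    y = np.asarray(labels).astype(int)
    yhat = np.asarray(predicted).astype(int)
    classes = np.unique(np.concatenate([y, yhat]))
    if classes.size < 2:
        raise ValueError("micro-averaging needs at least 2 classes")
    bin_y = np.concatenate([(y == c).astype(int) for c in classes])
    bin_yhat = np.concatenate([(yhat == c).astype(int) for c in classes])
    bin_scores = None
    if scores is not None:
        s = np.asarray(scores, dtype=float)
        if s.ndim != 2:
            raise ValueError("multiclass scores must be (n, n_classes)")
        bin_scores = np.concatenate([s[:, int(c)] for c in classes])
    return classification_metrics(bin_y, bin_yhat, bin_scores)


def regression_metrics(y, y_hat) -> RegressionReport:
    """MSE, MAE, and R^2 = 1 - SS_res/SS_tot (None for zero-variance y)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size < 2 or y.shape != y_hat.shape:
        raise ValueError("need >= 2 aligned observations")
    resid = y - y_hat
    mse = float(np.mean(resid**2))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("zero-variance target; R^2 undefined", stacklevel=2)
        r2 = None
    else:
        r2 = float(1.0 - np.sum(resid**2) / ss_tot)
    return RegressionReport(r2=r2, mse=mse, mae=mae, n=y.size)


def agreement_with_experiment(pred, exp) -> dict:
    """Percent agreement between binary prediction and experiment columns.

    Returns the exact percentage plus one-decimal and half-up integer
    renderings of the headline number.
    """
    p = np.asarray(pred).astype(int)
    e = np.asarray(exp).astype(int)
    if p.size == 0 or p.shape != e.shape:
        raise ValueError("columns must be non-empty and aligned")
    pct = 100.0 * float(np.sum(p == e)) / p.size
    return {
        "percent": pct,
        "percent_1dp": round(pct, 1),
        "percent_int": int(math.floor(pct + 0.5)),
        "n": int(p.size),
        "matches": int(np.sum(p == e)),
    }


@dataclass
class IterationSummary:
    per_iteration: list = field(default_factory=list)

    def mean(self, attr: str) -> float:
        vals = [getattr(r, attr) for r in self.per_iteration]
        vals = [v for v in vals if v is not None and not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")


def aggregate_reports(reports: list) -> IterationSummary:
    """Bundle per-iteration reports; means are plain arithmetic means."""
    return IterationSummary(per_iteration=list(reports))


def load_table2_fixture() -> pd.DataFrame:
    """The packaged 37-row zebrafish validation table.

    Columns: the two component chemicals with their tested concentrations
    (uM), the five model prediction columns, the zebrafish experimental
    outcome, and the called chemical interaction.
    """
    with resources.files("mixtox.data").joinpath("zebrafish_mixtures.csv").open() as fh:
        return pd.read_csv(fh)
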