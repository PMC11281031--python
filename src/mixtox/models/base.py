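from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

N_TOX_CLASSES = 5  # EPA acute-toxicity categories 0..4


class Task(str, enum.Enum):
    BINARY = "binary"
    MULTICLASS = "multiclass"
    REGRESSION = "regression"


@dataclass
class PredictionSet:
    """Aligned per-item model outputs.

    ``scores`` is a probability per item (binary), a (n, 5) row-stochastic
    matrix (multiclass), or the predicted log10(1/EC50 in mol/L)
    (regression). ``labels`` are thresholded at 0.5 / argmax; regression
    labels are the scores themselves.
    """

    mixture_ids: np.ndarray
    task: Task
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.mixture_ids = np.asarray(self.mixture_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels)
        n = self.mixture_ids.size
        if self.scores.shape[0] != n or self.labels.shape[0] != n:
            raise ValueError("ids, scores and labels must align")
        if self.task is Task.BINARY:
            if np.any(self.scores < 0) or np.any(self.scores > 1):
                raise ValueError("binary probabilities must lie in [0, 1]")
        elif self.task is Task.MULTICLASS:
            if self.scores.ndim != 2:
                raise ValueError("multiclass scores must be 2-D")
            if not np.allclose(self.scores.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("multiclass probability rows must sum to 1")


def labels_from_scores(task: Task, scores: np.ndarray) -> np.ndarray:
    if task is Task.BINARY:
        return (scores >= 0.5).astype(int)
    if task is Task.MULTICLASS:
        return np.argmax(scores, axis=1)
    return scores


def check_aligned(sets: list[PredictionSet], task: Task) -> np.ndarray:
    if not sets:
        raise ValueError("no prediction sets given")
    ids = sets[0].mixture_ids
    for ps in sets:
        if ps.task is not task:
            raise ValueError(f"expected task {task.value}, got {ps.task.value}")
        if ps.mixture_ids.shape != ids.shape or np.any(ps.mixture_ids != ids):
            raise ValueError("prediction sets are not aligned on mixture_ids")
    return ids
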