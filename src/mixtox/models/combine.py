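"""Model combination: the 4-model soft-voting ensemble and the 7-model
regression consensus."""

from __future__ import annotations

import numpy as np

from mixtox.models.base import PredictionSet, Task, check_aligned

__all__ = ["ensemble_predict", "consensus_regression"]


def ensemble_predict(
    predictions: list[PredictionSet],
    voting: str = "soft",
) -> PredictionSet:
    """Combine binary predictions from the HNN, RF, bagging, and AdaBoost.

    Soft voting (default) averages the four probabilities and thresholds the
    mean at 0.5 (a mean of exactly 0.5 is labelled toxic); hard voting takes
    the majority of member labels with the same >= 0.5 tie rule.
    """
    if len(predictions) != 4:
        raise ValueError(f"the ensemble expects 4 members, got {len(predictions)}")
    ids = check_aligned(predictions, Task.BINARY)
    if voting == "soft":
        scores = np.mean([p.scores for p in predictions], axis=0)
    elif voting == "hard":
        scores = np.mean([p.labels.astype(float) for p in predictions], axis=0)
    else:
        raise ValueError(f"voting must be 'soft' or 'hard', got {voting!r}")
    return PredictionSet(
        mixture_ids=ids, task=Task.BINARY,
        scores=scores, labels=(scores >= 0.5).astype(int),
    )


def consensus_regression(predictions: list[PredictionSet]) -> PredictionSet:
    """Arithmetic mean of the seven regressors' predicted log-potencies."""
    if len(predictions) != 7:
        raise ValueError(f"the consensus expects 7 members, got {len(predictions)}")
    ids = check_aligned(predictions, Task.REGRESSION)
    scores = np.mean([p.scores for p in predictions], axis=0)
    return PredictionSet(
        mixture_ids=ids, task=Task.REGRESSION, scores=scores, labels=scores,
    )
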