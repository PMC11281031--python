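"""Zebrafish-embryo teratogenicity scoring and interaction calls.

Each fish in a well is scored 0-4 (dead = 0; severely deformed = 1;
deformed = 2; slightly deformed = 3; normal = 4); the well score is the sum
over the (usually five) fish and the condition score the mean over replicate
wells. A mixture's interaction with its two single-chemical conditions is
called by comparing the combined condition score with the singles: a
combined score near the worse single indicates no interaction, far below it
additivity or (below the additive expectation) synergy, and above it
antagonism. The numeric margins are an explicit reconstruction — the label
set and the worked example (singles 17 and 15, combined 15 -> no
interaction) are fixed, the boundaries are configurable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "InteractionLabel",
    "InteractionCall",
    "well_score",
    "condition_score",
    "call_interaction",
    "ec50_from_scores",
]

MAX_FISH_SCORE = 4


class InteractionLabel(str, enum.Enum):
    SYNERGISTIC = "synergistic"
    ADDITIVE = "additive"
    NO_INTERACTION = "no_interaction"
    INCONCLUSIVE = "inconclusive"
    ANTAGONISTIC = "antagonistic"


@dataclass
class InteractionCall:
    label: InteractionLabel
    score_1: float
    score_2: float
    combined: float
    margin: float
    additive_expectation: float


def well_score(fish_scores: Sequence[int]) -> int:
    """Sum of the per-fish scores in one well (1-8 fish, each 0-4)."""
    if not 1 <= len(fish_scores) <= 8:
        raise ValueError(f"expected 1-8 fish per well, got {len(fish_scores)}")
    for s in fish_scores:
        if s not in (0, 1, 2, 3, 4):
            raise ValueError(f"illegal fish score {s!r}; must be 0-4")
    return int(sum(fish_scores))


def condition_score(well_sums: Sequence[float]) -> float:
    """Mean well score over the replicate wells of one condition."""
    if len(well_sums) == 0:
        raise ValueError("at least one well required")
    return float(np.mean(well_sums))


def call_interaction(
    score_1: float,
    score_2: float,
    combined: float,
    margin: float = 1.0,
    n_fish: int = 5,
) -> InteractionCall:
    """Classify the mixture interaction from condition scores.

    With m = min(score_1, score_2) and the additive expectation
    E = max(0, score_1 + score_2 - scale_max) (scale_max = 4 x n_fish):

    * |combined - m| <= margin         -> no interaction
    * combined > m + margin            -> antagonistic (mixture less toxic)
    * combined < m - margin:
        - E within the no-interaction band (E >= m - margin): the additive
          expectation is indistinguishable from no interaction, so the drop
          cannot be attributed                     -> inconclusive
        - combined < E - margin                    -> synergistic
        - otherwise                                -> additive

    Symmetric in (score_1, score_2); higher scores mean healthier fish.
    """
    scale_max = MAX_FISH_SCORE * n_fish
    for name, s in (("score_1", score_1), ("score_2", score_2),
                    ("combined", combined)):
        if not 0 <= s <= scale_max:
            raise ValueError(
                f"{name}={s} outside the 0-{scale_max} scale for {n_fish} fish"
            )
    if margin < 0:
        raise ValueError("margin must be >= 0")
    m = min(score_1, score_2)
    expect = max(0.0, score_1 + score_2 - scale_max)
    if combined > m + margin:
        label = InteractionLabel.ANTAGONISTIC
    elif abs(combined - m) <= margin:
        label = InteractionLabel.NO_INTERACTION
    elif expect >= m - margin:
        label = InteractionLabel.INCONCLUSIVE
    elif combined < expect - margin:
        label = InteractionLabel.SYNERGISTIC
    else:
        label = InteractionLabel.ADDITIVE
    return InteractionCall(
        label=label, score_1=score_1, score_2=score_2, combined=combined,
        margin=margin, additive_expectation=expect,
    )


def ec50_from_scores(
    doses: Sequence[float],
    scores: Sequence[float],
    threshold: float = 5.0,
) -> float:
    """Dose at which the monotone score curve crosses the EC50 threshold.

    The developmental-toxicity EC50 is the dose where the condition score
    falls to the threshold (5 on the 0-20 five-fish scale). Scores are
    assumed non-increasing in dose; the crossing is linearly interpolated
    between the bracketing tested doses.
    """
    d = np.asarray(doses, dtype=float)
    s = np.asarray(scores, dtype=float)
    if d.size != s.size or d.size < 2:
        raise ValueError("need >= 2 aligned (dose, score) points")
    order = np.argsort(d)
    d, s = d[order], s[order]
    if s[0] <= threshold:
        return float(d[0])
    below = np.nonzero(s <= threshold)[0]
    if below.size == 0:
        raise ValueError(
            f"score never reaches {threshold} within the tested doses"
        )
    j = below[0]
    i = j - 1
    if s[i] == s[j]:
        return float(d[j])
    frac = (s[i] - threshold) / (s[i] - s[j])
    return float(d[i] + frac * (d[j] - d[i]))
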