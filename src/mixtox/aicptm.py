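"""Combined AI + pathophysiology (AI-CPTM) scoring and ranking.

The total score adds four normalised components: the learner's binary
toxicity call (0/1), a categorical score from the IARC-style group
(1 -> 1, 2A -> 0.75, 2B -> 0.5, 3 -> 0.25, 4 -> 0), a potency score from the
daily-dose band, and the externally supplied pathophysiology Z score. With
every component normalised to 1, the total cannot exceed 4; a typical highly
toxic item scores (1 + 1 + 1) + (>0.9) = >3.9. Items are ranked by
descending total, and top-k retrieval counts the fraction of known-toxic
items among the k highest-ranked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LEGAL_COMPONENT_SCORES",
    "AICPTMRecord",
    "RankedList",
    "categorical_score",
    "potency_score",
    "total_score",
    "normalize_z",
    "rank_items",
    "topk_retrieval",
    "score_table",
]

#: Legal values for the categorical and potency components.
LEGAL_COMPONENT_SCORES = (0.0, 0.25, 0.5, 0.75, 1.0)

_GROUP_SCORES = {"1": 1.0, "2A": 0.75, "2B": 0.5, "3": 0.25, "4": 0.0}


def categorical_score(group: str) -> float:
    """Score for the IARC-style hazard group (1, 2A, 2B, 3, 4)."""
    key = str(group).strip().upper()
    if key not in _GROUP_SCORES:
        raise ValueError(
            f"unknown group {group!r}; expected one of {list(_GROUP_SCORES)}"
        )
    return _GROUP_SCORES[key]


def potency_score(dose: float) -> float:
    """Score for a daily dose in mg/kg/day.

    Bands: <100 -> 1; [100, 250) -> 0.75; [250, 500) -> 0.5;
    [500, 1500) -> 0.25; >=1500 -> 0. Boundary doses join the more-toxic
    (higher-score) band.
    """
    if dose <= 0 or not np.isfinite(dose):
        raise ValueError(f"dose must be positive and finite, got {dose}")
    if dose < 100:
        return 1.0
    if dose < 250:
        return 0.75
    if dose < 500:
        return 0.5
    if dose < 1500:
        return 0.25
    return 0.0


def total_score(binary: float, categorical: float, potency: float, z: float) -> float:
    """Exact component sum: binary + categorical + potency + z.

    Monotone non-decreasing in every argument; at most 4 whenever z <= 1.
    """
    if binary not in (0, 1, 0.0, 1.0):
        raise ValueError(f"binary score must be 0 or 1, got {binary}")
    for name, val in (("categorical", categorical), ("potency", potency)):
        if val not in LEGAL_COMPONENT_SCORES:
            raise ValueError(
                f"{name} score must be one of {LEGAL_COMPONENT_SCORES}, got {val}"
            )
    if not np.isfinite(z):
        raise ValueError(f"z score must be finite, got {z}")
    return float(binary) + float(categorical) + float(potency) + float(z)


def normalize_z(z_scores) -> np.ndarray:
    """Min-max scale a batch of Z scores to [0, 1] (constant batch -> 0)."""
    z = np.asarray(z_scores, dtype=float)
    lo, hi = z.min(), z.max()
    if hi == lo:
        return np.zeros_like(z)
    return (z - lo) / (hi - lo)


@dataclass
class AICPTMRecord:
    item_id: str
    binary_score: int
    categorical_score: float
    potency_score: float
    z_score: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = total_score(
            self.binary_score, self.categorical_score,
            self.potency_score, self.z_score,
        )


@dataclass
class RankedList:
    item_ids: list[str]
    totals: list[float]
    tie_rule: str = "item_id ascending"
    labels: list[int] | None = None

    def __post_init__(self) -> None:
        if any(a < b for a, b in zip(self.totals, self.totals[1:])):
            raise ValueError("totals must be non-increasing")


def rank_items(records: list[AICPTMRecord], labels: dict[str, int] | None = None) -> RankedList:
    """Order items by descending total; ties break on item_id (ascending)."""
    order = sorted(records, key=lambda r: (-r.total, r.item_id))
    return RankedList(
        item_ids=[r.item_id for r in order],
        totals=[r.total for r in order],
        labels=[labels[r.item_id] for r in order] if labels else None,
    )


def topk_retrieval(ranked: RankedList, k: int, labels=None) -> float:
    """Percent of label-1 items among the top k of the ranking."""
    lab = labels if labels is not None else ranked.labels
    if lab is None:
        raise ValueError("labels required for retrieval")
    lab = np.asarray(lab)
    if lab.size != len(ranked.item_ids):
        raise ValueError("labels must align with the ranked list")
    if not (1 <= k <= lab.size):
        raise ValueError(f"k must be in 1..{lab.size}, got {k}")
    return float(100.0 * lab[:k].sum() / k)


def score_table(df: pd.DataFrame) -> pd.DataFrame:
    """Score a table with columns item_id, binary_score, group,
    dose_mg_kg_day, z_score; returns it with categorical_score,
    potency_score, total, and rank columns added."""
    required = {"item_id", "binary_score", "group", "dose_mg_kg_day", "z_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = df.copy()
    out["categorical_score"] = [categorical_score(g) for g in out["group"]]
    out["potency_score"] = [potency_score(d) for d in out["dose_mg_kg_day"]]
    out["total"] = [
        total_score(b, c, p, z)
        for b, c, p, z in zip(out["binary_score"], out["categorical_score"],
                              out["potency_score"], out["z_score"])
    ]
    order = out.sort_values(
        ["total", "item_id"], ascending=[False, True]
    ).index
    ranks = pd.Series(np.arange(1, len(out) + 1), index=order)
    out["rank"] = ranks
    return out
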