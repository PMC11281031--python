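"""Assumption-based virtual mixture datasets.

Binary mixtures are generated from labelled single-chemical pools under the
labelling hypothesis that toxic+toxic and toxic+nontoxic pairs are toxic
while nontoxic+nontoxic pairs are non-toxic. Two pairing conventions are
exposed: disjoint unique pairing (each chemical used at most once, floor(n/2)
pairs) and uniform sampling of unordered pairs without replacement. Pools may
first be narrowed to chemicals structurally similar (Tanimoto > 0.6 by
default) to a reference set.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mixtox.core_chem import ChemicalRecord

__all__ = [
    "Case",
    "ChemicalPool",
    "VirtualMixtureDataset",
    "disjoint_pairing",
    "label_hypothesis",
    "tanimoto_similarity",
    "tanimoto_filter",
    "sample_combinations",
    "build_dataset_vii",
    "concat_datasets",
]


class Case(str, enum.Enum):
    TOXIC_TOXIC = "toxic_toxic"
    NONTOXIC_NONTOXIC = "nontoxic_nontoxic"
    MIXED = "mixed"


@dataclass
class ChemicalPool:
    """Labelled chemicals, optionally with binary fingerprints."""

    records: list[ChemicalRecord]
    labels: dict[str, int]
    fingerprints: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.chem_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate chem_ids in pool")
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise ValueError(f"labels missing for {missing[:5]}...")

    @property
    def ids(self) -> list[str]:
        return [r.chem_id for r in self.records]

    def subset(self, keep: Iterable[str]) -> "ChemicalPool":
        keep = set(keep)
        return ChemicalPool(
            records=[r for r in self.records if r.chem_id in keep],
            labels={i: l for i, l in self.labels.items() if i in keep},
            fingerprints={i: f for i, f in self.fingerprints.items() if i in keep},
        )


@dataclass
class VirtualMixtureDataset:
    pairs: list[tuple[str, str]]
    labels: list[int]
    case_tags: list[str]
    seed: int | None = None
    source_tags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.pairs)
        return pd.DataFrame({
            "mixture_id": [f"vm{i}" for i in range(n)],
            "chem_id_1": [p[0] for p in self.pairs],
            "chem_id_2": [p[1] for p in self.pairs],
            "label": self.labels,
            "case_tag": self.case_tags,
            "source_tag": self.source_tags or ["virtual"] * n,
            "seed": self.seed,
        })


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def disjoint_pairing(pool_ids: Sequence[str], seed: int = 0) -> list[tuple[str, str]]:
    """Uniquely pair a pool: floor(n/2) pairs, every id used at most once.

    The pool is shuffled with the seed and consecutive ids paired; one id is
    left unpaired when n is odd.
    """
    ids = list(pool_ids)
    if not ids:
        raise ValueError("pool is empty")
    if len(ids) < 2:
        warnings.warn("pool has fewer than 2 chemicals; no pairs formed",
                      stacklevel=2)
        return []
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return [
        _norm_pair(ids[order[2 * i]], ids[order[2 * i + 1]])
        for i in range(len(ids) // 2)
    ]


def label_hypothesis(case: Case | str) -> int:
    """Mixture label under the case assumption: only nontoxic+nontoxic is 0."""
    case = Case(case)
    return 0 if case is Case.NONTOXIC_NONTOXIC else 1


def tanimoto_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto(a, b) = |a AND b| / |a OR b| over binary fingerprints.

    Defined as 0 when either fingerprint is all zeros.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_filter(
    pool: ChemicalPool,
    refs: Sequence[np.ndarray],
    threshold: float = 0.6,
) -> ChemicalPool:
    """Keep chemicals whose max similarity to any reference is > threshold."""
    if not refs:
        raise ValueError("no reference fingerprints given")
    ref_mat = np.asarray([np.asarray(r, dtype=bool) for r in refs])
    keep = []
    for cid in pool.ids:
        fp = pool.fingerprints.get(cid)
        if fp is None:
            raise ValueError(f"fingerprint missing for {cid}")
        fp = np.asarray(fp, dtype=bool)
        if not fp.any():
            warnings.warn(f"zero fingerprint for {cid}; similarity 0",
                          stacklevel=2)
            continue
        inter = np.logical_and(ref_mat, fp).sum(axis=1)
        union = np.logical_or(ref_mat, fp).sum(axis=1)
        sims = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        if sims.max() > threshold:
            keep.append(cid)
    return pool.subset(keep)


def _n_available(pool_a: Sequence[str], pool_b: Sequence[str] | None) -> int:
    if pool_b is None:
        n = len(pool_a)
        return n * (n - 1) // 2
    a, b = set(pool_a), set(pool_b)
    overlap = len(a & b)
    return len(a) * len(b) - overlap * (overlap + 1) // 2


def sample_combinations(
    pool_a: Sequence[str],
    pool_b: Sequence[str] | None,
    n: int,
    seed: int = 0,
    exclude: Iterable[tuple[str, str]] = (),
) -> list[tuple[str, str]]:
    """Draw n distinct unordered pairs uniformly without replacement.

    ``pool_b=None`` samples within ``pool_a`` (pairs of two distinct
    chemicals); otherwise one id comes from each pool. Pairs listed in
    ``exclude`` (unordered) are never returned.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    a = list(pool_a)
    b = list(pool_b) if pool_b is not None else None
    excluded = {_norm_pair(x, y) for x, y in exclude}
    available = _n_available(a, b) - len(excluded)
    if n > available:
        raise ValueError(
            f"requested {n} pairs but only {available} are available"
        )
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    # rejection sampling; vectorized draws keep this fast even near saturation
    while len(out) < n:
        batch = max(1024, 2 * (n - len(out)))
        if b is None:
            ii = rng.integers(0, len(a), size=batch)
            jj = rng.integers(0, len(a), size=batch)
        else:
            ii = rng.integers(0, len(a), size=batch)
            jj = rng.integers(0, len(b), size=batch)
        for i, j in zip(ii, jj):
            x = a[i]
            y = a[j] if b is None else b[j]
            if x == y:
                continue
            p = _norm_pair(x, y)
            if p in chosen or p in excluded:
                continue
            chosen.add(p)
            out.append(p)
            if len(out) == n:
                break
    return out


def build_dataset_vii(
    toxic_pool: Sequence[str],
    nontoxic_pool: Sequence[str],
    counts: tuple[int, int, int] = (30_000, 60_000, 60_000),
    seed: int = 0,
) -> VirtualMixtureDataset:
    """Stratified virtual dataset: (toxic+toxic, nontoxic+nontoxic, mixed).

    ``counts`` gives the number of pairs per stratum; with the defaults the
    result carries 90,000 toxic and 60,000 non-toxic labels.
    """
    n_tt, n_nn, n_mix = counts
    tt = sample_combinations(toxic_pool, None, n_tt, seed=seed)
    nn = sample_combinations(nontoxic_pool, None, n_nn, seed=seed + 1)
    mixed = sample_combinations(
        toxic_pool, nontoxic_pool, n_mix, seed=seed + 2,
        exclude=tt + nn,
    )
    pairs = tt + nn + mixed
    cases = (
        [Case.TOXIC_TOXIC.value] * n_tt
        + [Case.NONTOXIC_NONTOXIC.value] * n_nn
        + [Case.MIXED.value] * n_mix
    )
    labels = [label_hypothesis(c) for c in cases]
    return VirtualMixtureDataset(pairs=pairs, labels=labels,
                                 case_tags=cases, seed=seed)


def concat_datasets(
    datasets: Sequence[VirtualMixtureDataset],
    source_tags: Sequence[str] | None = None,
) -> VirtualMixtureDataset:
    """Concatenate datasets with provenance tags, deduplicating unordered pairs."""
    if source_tags is not None and len(source_tags) != len(datasets):
        raise ValueError("one source tag per dataset required")
    seen: set[tuple[str, str]] = set()
    pairs, labels, cases, sources = [], [], [], []
    for k, ds in enumerate(datasets):
        tag = source_tags[k] if source_tags else f"dataset{k}"
        own = ds.source_tags or [tag] * len(ds.pairs)
        for p, l, c, s in zip(ds.pairs, ds.labels, ds.case_tags, own):
            p = _norm_pair(*p)
            if p in seen:
                continue
            seen.add(p)
            pairs.append(p)
            labels.append(l)
            cases.append(c)
            sources.append(s)
    return VirtualMixtureDataset(pairs=pairs, labels=labels, case_tags=cases,
                                 source_tags=sources)
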