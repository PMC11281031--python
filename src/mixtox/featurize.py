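"""Model-input construction.

Two feature families feed the hybrid network: a dose-weighted combination of
the components' molecular descriptor vectors (the mixture descriptor D), and
a one-hot encoded tensor over the characters of the concatenated mixture
SMILES. Mixture SMILES join the component strings with the standard
multi-component separator '.'; the character vocabulary is built in
first-appearance order over the training corpus and serialized with models so
prediction-time encoding is identical.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorVector",
    "MixMethod",
    "WeightBasis",
    "MixtureDescriptor",
    "SmilesVocabulary",
    "OneHotTensor",
    "concat_mixture_smiles",
    "build_vocabulary",
    "one_hot_encode",
    "save_tensor",
    "load_tensor",
    "mix_descriptors",
    "impute_descriptors",
    "normalize_component_order",
]


@dataclass
class DescriptorVector:
    chem_id: str
    values: np.ndarray
    names: list[str]
    backend: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.names) != self.values.size:
            raise ValueError("descriptor names must match values 1:1")
        if len(set(self.names)) != len(self.names):
            raise ValueError("descriptor names must be unique")


class MixMethod(str, enum.Enum):
    SUM = "sum"
    DIFF = "diff"
    NORM = "norm"


class WeightBasis(str, enum.Enum):
    """What the mixing weights x_i represent."""

    MOLE = "mole"
    MASS_CONC = "mass_conc"
    EQUAL = "equal"


@dataclass
class MixtureDescriptor:
    mixture_id: str
    method: MixMethod
    weights: tuple[float, float]
    values: np.ndarray
    basis: WeightBasis = WeightBasis.MASS_CONC
    names: list[str] = field(default_factory=list)


def concat_mixture_smiles(s1: str, s2: str) -> str:
    """Mixture SMILES S = S1.S2 (ordered concatenation, '.' separator)."""
    if not s1 or not s2:
        raise ValueError("component SMILES must be non-empty")
    return f"{s1}.{s2}"


def normalize_component_order(
    id1: str, id2: str, *payloads: tuple
) -> tuple:
    """Lexicographically order a binary mixture's components.

    Each payload is a pair aligned with (id1, id2); payloads are swapped in
    lock-step when the ids are, so mixtures are order-invariant end to end.
    """
    if id1 <= id2:
        return (id1, id2, *payloads)
    return (id2, id1, *(tuple(reversed(p)) for p in payloads))


@dataclass
class SmilesVocabulary:
    """Character -> index map (1..M, contiguous, first-appearance order)."""

    char_to_index: dict[str, int]

    def __post_init__(self) -> None:
        idx = sorted(self.char_to_index.values())
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("indices must form a contiguous 1..M bijection")

    @property
    def size(self) -> int:
        return len(self.char_to_index)

    @property
    def index_to_char(self) -> dict[int, str]:
        return {i: c for c, i in self.char_to_index.items()}

    def to_json(self) -> str:
        return json.dumps(self.char_to_index)

    @classmethod
    def from_json(cls, s: str) -> "SmilesVocabulary":
        return cls(json.loads(s))


def build_vocabulary(corpus: Iterable[str]) -> SmilesVocabulary:
    """Index every character of the corpus in order of first appearance."""
    corpus = list(corpus)
    if not corpus:
        raise ValueError("corpus must be non-empty")
    mapping: dict[str, int] = {}
    for s in corpus:
        for ch in s:
            if ch not in mapping:
                mapping[ch] = len(mapping) + 1
    return SmilesVocabulary(mapping)


@dataclass
class OneHotTensor:
    """K x L x M binary array over K strings, max length L, vocabulary M."""

    data: np.ndarray
    lengths: np.ndarray
    vocab: SmilesVocabulary

    @property
    def K(self) -> int:
        return self.data.shape[0]

    @property
    def L(self) -> int:
        return self.data.shape[1]

    @property
    def M(self) -> int:
        return self.data.shape[2]

    def decode(self) -> list[str]:
        """Recover the original strings (inverse of :func:`one_hot_encode`)."""
        rev = self.vocab.index_to_char
        out = []
        for k in range(self.K):
            n = int(self.lengths[k])
            idx = np.argmax(self.data[k, :n, :], axis=1) + 1
            out.append("".join(rev[int(i)] for i in idx))
        return out


def save_tensor(tensor: "OneHotTensor", path) -> None:
    """Persist an encoded tensor as an .npz with a JSON sidecar (vocab, L,
    lengths) so prediction-time encoding can be reproduced exactly."""
    import pathlib

    path = pathlib.Path(path)
    np.savez_compressed(path, data=tensor.data, lengths=tensor.lengths)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "vocab": tensor.vocab.char_to_index,
        "L": int(tensor.L),
        "lengths": tensor.lengths.tolist(),
    }))


def load_tensor(path) -> "OneHotTensor":
    import pathlib

    path = pathlib.Path(path)
    arrays = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return OneHotTensor(
        data=arrays["data"], lengths=arrays["lengths"],
        vocab=SmilesVocabulary(meta["vocab"]),
    )


def one_hot_encode(
    strings: Sequence[str],
    vocab: SmilesVocabulary,
    L: int | None = None,
) -> OneHotTensor:
    """One-hot encode strings: row j of slice k is hot at vocab[s_k[j]] - 1.

    Strings shorter than L are zero-padded at the tail (no pad token);
    longer strings or out-of-vocabulary characters raise.
    """
    strings = list(strings)
    if not strings:
        raise ValueError("no strings to encode")
    if any(not s for s in strings):
        raise ValueError("empty string cannot be encoded")
    max_len = max(len(s) for s in strings)
    if L is None:
        L = max_len
    elif max_len > L:
        raise ValueError(f"string of length {max_len} exceeds L={L}")
    data = np.zeros((len(strings), L, vocab.size), dtype=np.uint8)
    for k, s in enumerate(strings):
        for j, ch in enumerate(s):
            idx = vocab.char_to_index.get(ch)
            if idx is None:
                raise ValueError(
                    f"character {ch!r} at position {j} of string {k} "
                    "is not in the vocabulary"
                )
            data[k, j, idx - 1] = 1
    lengths = np.array([len(s) for s in strings], dtype=int)
    return OneHotTensor(data=data, lengths=lengths, vocab=vocab)


def mix_descriptors(
    method: MixMethod | str,
    weights: tuple[float, float],
    d1: DescriptorVector,
    d2: DescriptorVector,
    mixture_id: str = "",
    basis: WeightBasis = WeightBasis.MASS_CONC,
) -> MixtureDescriptor:
    """Dose-weighted mixture descriptor D from two component vectors.

    ``sum`` (the reported method) is D = x1 d1 + x2 d2; ``diff`` is the
    elementwise |x1 d1 - x2 d2| and ``norm`` the elementwise
    sqrt((x1 d1)^2 + (x2 d2)^2) — both documented reconstructions.
    """
    method = MixMethod(method)
    if d1.names != d2.names:
        raise ValueError("descriptor name/order mismatch between components")
    x1, x2 = float(weights[0]), float(weights[1])
    if x1 < 0 or x2 < 0 or abs(x1 + x2 - 1.0) > 1e-9:
        raise ValueError(f"weights must be >= 0 and sum to 1, got {weights}")
    a, b = x1 * d1.values, x2 * d2.values
    if method is MixMethod.SUM:
        values = a + b
    elif method is MixMethod.DIFF:
        values = np.abs(a - b)
    else:
        values = np.sqrt(a**2 + b**2)
    if not np.all(np.isfinite(values)):
        raise ValueError("mixture descriptor contains non-finite values")
    return MixtureDescriptor(
        mixture_id=mixture_id, method=method, weights=(x1, x2),
        values=values, basis=basis, names=list(d1.names),
    )


def impute_descriptors(matrix: pd.DataFrame) -> pd.DataFrame:
    """Median-impute non-finite entries; drop all-NaN columns with a warning.

    ``matrix`` is chemicals x descriptors; the per-descriptor median over
    chemicals replaces NaN/inf, and the output is guaranteed finite.
    """
    if matrix.empty:
        raise ValueError("descriptor matrix is empty")
    out = matrix.replace([np.inf, -np.inf], np.nan).astype(float)
    dead = [c for c in out.columns if out[c].isna().all()]
    if dead:
        warnings.warn(
            f"dropping {len(dead)} all-NaN descriptor column(s): {dead[:5]}...",
            stacklevel=2,
        )
        out = out.drop(columns=dead)
    out = out.fillna(out.median())
    assert np.isfinite(out.to_numpy()).all()
    return out
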