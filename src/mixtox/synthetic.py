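"""Self-contained synthetic chemical pools and mixture datasets.

The generator emulates the statistical structure the mixture-toxicity
pipeline assumes: two chemical populations (toxic / non-toxic) whose
descriptor distributions are Gaussian with class means separated by a
configurable effect size (in pooled-SD units, unit or equicorrelated
covariance), log-normally distributed single-chemical potencies whose class
parameters keep labels consistent with the 100 mg/L rule for >= 99% of
draws at the defaults, random tokenizable SMILES-like strings over a fixed
alphabet (not chemically valid molecules), and random-bit fingerprints.
Mixture sets are labelled either by the case hypothesis or through the
concentration-addition model, so regression targets have a recoverable
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mixtox import ca_model
from mixtox.core_chem import ChemicalRecord
from mixtox.virtual_mixtures import Case, ChemicalPool, label_hypothesis

__all__ = ["SyntheticConfig", "SyntheticPool", "generate_pool",
           "generate_mixture_set"]


@dataclass
class SyntheticConfig:
    n_toxic: int = 200
    n_nontoxic: int = 200
    n_desc: int = 20
    effect_size: float = 3.0           # class mean separation, pooled-SD units
    # log10 mg/L potency parameters per class
    mu_log10_toxic: float = 0.5
    mu_log10_nontoxic: float = 3.0
    sigma_log10: float = 0.4
    equicorrelation: float = 0.0       # optional descriptor collinearity
    smiles_alphabet: str = "CNOSPF=#()123"
    min_len: int = 4
    max_len: int = 20
    fp_bits: int = 256
    fp_density: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_toxic < 0 or self.n_nontoxic < 0:
            raise ValueError("counts must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.sigma_log10 <= 0:
            raise ValueError("sigma_log10 must be > 0")
        if not 0 <= self.equicorrelation < 1:
            raise ValueError("equicorrelation must be in [0, 1)")
        if not 2 <= self.min_len <= self.max_len:
            raise ValueError("need 2 <= min_len <= max_len")


@dataclass
class SyntheticPool:
    """A labelled pool plus its descriptor matrix and potency table."""

    pool: ChemicalPool
    descriptors: pd.DataFrame          # chem_id x descriptor columns
    ec50_mg_L: dict[str, float]
    config: SyntheticConfig = field(repr=False, default=None)


def _random_smiles(rng: np.random.Generator, cfg: SyntheticConfig) -> str:
    length = int(rng.integers(cfg.min_len, cfg.max_len + 1))
    chars = rng.integers(0, len(cfg.smiles_alphabet), size=length)
    return "".join(cfg.smiles_alphabet[i] for i in chars)


def generate_pool(cfg: SyntheticConfig) -> SyntheticPool:
    """Draw a reproducible two-class chemical pool.

    Toxic chemicals draw descriptors from mean +effect_size/2 and non-toxic
    from -effect_size/2 (per descriptor); potencies are 10**N(mu, sigma) in
    mg/L with class-specific mu.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_toxic + cfg.n_nontoxic
    labels_arr = np.array([1] * cfg.n_toxic + [0] * cfg.n_nontoxic)

    shift = np.where(labels_arr == 1, cfg.effect_size / 2, -cfg.effect_size / 2)
    z = rng.standard_normal((n, cfg.n_desc))
    if cfg.equicorrelation > 0:
        rho = cfg.equicorrelation
        common = rng.standard_normal((n, 1))
        z = np.sqrt(rho) * common + np.sqrt(1 - rho) * z
    desc = z + shift[:, None]

    mu = np.where(labels_arr == 1, cfg.mu_log10_toxic, cfg.mu_log10_nontoxic)
    ec50 = 10.0 ** rng.normal(mu, cfg.sigma_log10)

    records, fingerprints, ec50_map = [], {}, {}
    ids = [f"syn{i:05d}" for i in range(n)]
    for i, cid in enumerate(ids):
        records.append(ChemicalRecord(
            chem_id=cid,
            name=f"synthetic-{i}",
            smiles=_random_smiles(rng, cfg),
            molar_mass=float(10.0 ** rng.normal(2.5, 0.2)),  # ~300 g/mol
        ))
        fingerprints[cid] = (
            rng.random(cfg.fp_bits) < cfg.fp_density
        ).astype(np.uint8)
        ec50_map[cid] = float(ec50[i])

    pool = ChemicalPool(
        records=records,
        labels=dict(zip(ids, labels_arr.tolist())),
        fingerprints=fingerprints,
    )
    descriptors = pd.DataFrame(
        desc, index=pd.Index(ids, name="chem_id"),
        columns=[f"d{j}" for j in range(cfg.n_desc)],
    )
    return SyntheticPool(pool=pool, descriptors=descriptors,
                         ec50_mg_L=ec50_map, config=cfg)


def generate_mixture_set(
    syn: SyntheticPool,
    n_mixtures: int,
    labeling: str = "hypothesis",
    seed: int = 0,
) -> pd.DataFrame:
    """Sample binary mixtures from the pool and label them.

    ``hypothesis`` labelling applies the case rule to the component class
    labels; ``ca_model`` computes the concentration-addition mixture EC50
    at equal mass fractions and applies the 100 mg/L cutoff, recording the
    EC50_mix so regression targets are recoverable. Component order is
    normalised lexicographically.
    """
    if labeling not in ("hypothesis", "ca_model"):
        raise ValueError(f"unknown labeling {labeling!r}")
    ids = syn.pool.ids
    if len(ids) < 2:
        raise ValueError("pool too small to form mixtures")
    rng = np.random.default_rng(seed)
    rows = []
    seen: set[tuple[str, str]] = set()
    max_pairs = len(ids) * (len(ids) - 1) // 2
    if n_mixtures > max_pairs:
        raise ValueError(f"requested {n_mixtures} pairs, only {max_pairs} exist")
    while len(rows) < n_mixtures:
        i, j = rng.integers(0, len(ids), size=2)
        if i == j:
            continue
        a, b = sorted((ids[i], ids[j]))
        if (a, b) in seen:
            continue
        seen.add((a, b))
        la, lb = syn.pool.labels[a], syn.pool.labels[b]
        ea, eb = syn.ec50_mg_L[a], syn.ec50_mg_L[b]
        ec50_mix = ca_model.mixture_ec50_ca([0.5, 0.5], [ea, eb])
        if labeling == "hypothesis":
            if la and lb:
                case = Case.TOXIC_TOXIC
            elif not la and not lb:
                case = Case.NONTOXIC_NONTOXIC
            else:
                case = Case.MIXED
            label = label_hypothesis(case)
            tag = case.value
        else:
            label = int(ec50_mix < 100.0)
            tag = "ca_model"
        rows.append({
            "mixture_id": f"mix{len(rows):05d}",
            "chem_id_1": a, "chem_id_2": b,
            "mass_fraction_1": 0.5, "mass_fraction_2": 0.5,
            "ec50_1_mg_L": ea, "ec50_2_mg_L": eb,
            "ec50_mix_mg_L": ec50_mix,
            "label": label, "case_tag": tag, "seed": seed,
        })
    return pd.DataFrame(rows)
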