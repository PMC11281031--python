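"""Concentration-addition (CA) mixture algebra.

Under concentration addition, components act through a common mode and the
mixture potency is the fraction-weighted harmonic combination of the
single-chemical potencies:

    EC50_mix = 1 / sum_i(p_i / EC50_i)

where p_i are mass fractions at the median effect. The joint action is
summarised by the toxic-unit sum TU = sum_i(C_i / EC50_i); the mixture
concentration producing the median effect is C_M = TU x EC50_mix, and within
the additive TU band the component concentrations required for the median
effect lie in (0.8 p_i EC50_mix, 1.2 p_i EC50_mix).

Interaction bands follow the source convention exactly: TU in [0.8, 1.2] is
additive, TU > 1.2 synergistic, TU <= 0.8 antagonistic (note this is the
reverse of the more common CA reading, where TU < 1 at equitoxicity would
suggest synergy), and TU >= 0.8 additionally flags independent action.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Interaction",
    "MixtureComposition",
    "CAResult",
    "toxic_units",
    "mixture_ec50_ca",
    "cm_from_tu",
    "component_conc_range",
    "classify_interaction_tu",
    "fractions_from_tu_ratio",
    "analyze_mixture",
    "ADDITIVE_TU_BAND",
]

#: Default TU band treated as additive.
ADDITIVE_TU_BAND = (0.8, 1.2)


class Interaction(str, enum.Enum):
    ADDITIVE = "additive"
    SYNERGISTIC = "synergistic"
    ANTAGONISTIC = "antagonistic"
    INDEPENDENT = "independent"
    UNCLASSIFIED = "unclassified"


def _as_positive(arr, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(a)) or np.any(a <= 0):
        raise ValueError(f"{name} must be positive and finite, got {a}")
    return a


def _check_fractions(fracs, name: str = "fractions") -> np.ndarray:
    f = np.asarray(fracs, dtype=float)
    if np.any(f < 0):
        raise ValueError(f"{name} must be non-negative, got {f}")
    dev = f.sum() - 1.0
    if abs(dev) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (deviation {dev:+.3e})")
    return f


@dataclass
class MixtureComposition:
    """Components of a (usually binary) mixture and their CA inputs."""

    component_ids: list[str]
    ec50_single: Sequence[float]                  # mg/L, acting alone
    conc: Sequence[float] | None = None           # mg/L at median effect
    mass_fraction: Sequence[float] | None = None
    mole_fraction: Sequence[float] | None = None
    tu_fraction: Sequence[float] | None = None

    def __post_init__(self) -> None:
        n = len(self.component_ids)
        if n < 2:
            raise ValueError("a mixture needs at least 2 components")
        _as_positive(self.ec50_single, "ec50_single")
        if len(self.ec50_single) != n:
            raise ValueError("ec50_single length must match component_ids")
        for name in ("mass_fraction", "mole_fraction", "tu_fraction"):
            v = getattr(self, name)
            if v is not None:
                if len(v) != n:
                    raise ValueError(f"{name} length must match component_ids")
                _check_fractions(v, name)


@dataclass
class CAResult:
    ec50_mix: float                               # mg/L
    tu: float | None
    c_m: float | None                             # mg/L
    conc_range: list[tuple[float, float]]         # per component, mg/L
    interaction: Interaction
    independent_action: bool = False


def toxic_units(conc, ec50_single) -> float:
    """Toxic-unit sum TU = sum_i C_i / EC50_i (dimensionless)."""
    c = _as_positive(conc, "conc")
    e = _as_positive(ec50_single, "ec50_single")
    if c.shape != e.shape:
        raise ValueError(f"length mismatch: {c.size} concentrations vs {e.size} EC50s")
    return float(np.sum(c / e))


def mixture_ec50_ca(mass_fractions, ec50_single) -> float:
    """CA-predicted mixture EC50 (mg/L): 1 / sum_i(p_i / EC50_i).

    The result is the p-weighted harmonic mean, hence always bounded by the
    smallest and largest component EC50.
    """
    p = _check_fractions(mass_fractions, "mass_fractions")
    e = _as_positive(ec50_single, "ec50_single")
    if p.shape != e.shape:
        raise ValueError(f"length mismatch: {p.size} fractions vs {e.size} EC50s")
    return float(1.0 / np.sum(p / e))


def cm_from_tu(tu: float, ec50_mix: float) -> float:
    """Mixture concentration at the median effect: C_M = TU x EC50_mix."""
    if tu <= 0 or not np.isfinite(tu):
        raise ValueError(f"TU must be positive and finite, got {tu}")
    if ec50_mix <= 0 or not np.isfinite(ec50_mix):
        raise ValueError(f"EC50_mix must be positive and finite, got {ec50_mix}")
    return tu * ec50_mix


def component_conc_range(
    mass_fractions,
    ec50_mix: float,
    tu_band: tuple[float, float] = ADDITIVE_TU_BAND,
) -> list[tuple[float, float]]:
    """Per-component concentration range causing the median mixture effect.

    Component i gets (lo x p_i x EC50_mix, hi x p_i x EC50_mix) with (lo, hi)
    the TU band, (0.8, 1.2) by default for the additive case. Bands other than
    the additive default model the corresponding interaction regime.
    """
    p = _check_fractions(mass_fractions, "mass_fractions")
    if ec50_mix <= 0 or not np.isfinite(ec50_mix):
        raise ValueError(f"EC50_mix must be positive and finite, got {ec50_mix}")
    lo, hi = tu_band
    if not (0 < lo <= hi):
        raise ValueError(f"invalid TU band {tu_band}")
    return [(float(lo * pi * ec50_mix), float(hi * pi * ec50_mix)) for pi in p]


def classify_interaction_tu(
    tu: float,
    tu_band: tuple[float, float] = ADDITIVE_TU_BAND,
) -> tuple[Interaction, bool]:
    """Classify the joint effect from the TU sum.

    Returns ``(primary, independent_flag)``. Precedence: antagonistic below
    the band, additive inside it (band edges included), synergistic above.
    The overlapping "independent action" band (TU >= lower edge) is reported
    as the boolean side flag rather than competing with the primary label.
    """
    if tu <= 0 or not np.isfinite(tu):
        raise ValueError(f"TU must be positive and finite, got {tu}")
    lo, hi = tu_band
    if tu < lo:
        primary = Interaction.ANTAGONISTIC
    elif tu <= hi:
        primary = Interaction.ADDITIVE
    else:
        primary = Interaction.SYNERGISTIC
    return primary, bool(tu >= lo)


def fractions_from_tu_ratio(tu_fractions, ec50_single, molar_mass):
    """Mass and mole fractions from toxic-unit ratios.

    Given the components' TU shares in the mixture and their single-chemical
    EC50s, the mass fraction of component i is

        w_i = tu_i EC50_i / sum_j tu_j EC50_j

    (the unique normalisation for which concentrations p_i x EC50_mix
    reproduce TU = 1), and mole fractions renormalise w_i / M_i.
    """
    t = np.asarray(tu_fractions, dtype=float)
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError(f"tu_fractions must be non-negative finite, got {t}")
    if t.sum() <= 0:
        raise ValueError("tu_fractions are all zero (degenerate mixture)")
    dev = t.sum() - 1.0
    if abs(dev) > 1e-9:
        raise ValueError(f"tu_fractions must sum to 1 (deviation {dev:+.3e})")
    e = _as_positive(ec50_single, "ec50_single")
    m = _as_positive(molar_mass, "molar_mass")
    if not (t.shape == e.shape == m.shape):
        raise ValueError("tu_fractions, ec50_single, molar_mass must align")
    w = t * e
    mass = w / w.sum()
    moles = mass / m
    mole = moles / moles.sum()
    return mass, mole


def analyze_mixture(
    comp: MixtureComposition,
    tu_band: tuple[float, float] = ADDITIVE_TU_BAND,
) -> CAResult:
    """Full CA analysis of a mixture composition.

    Mass fractions are taken directly if provided, else derived from TU
    ratios, else from observed concentrations; the TU sum requires observed
    concentrations and is otherwise left unset (interaction unclassified).
    """
    e = np.asarray(comp.ec50_single, dtype=float)
    if comp.mass_fraction is not None:
        p = np.asarray(comp.mass_fraction, dtype=float)
    elif comp.tu_fraction is not None:
        mm = np.ones_like(e)  # mole fractions unused here
        p, _ = fractions_from_tu_ratio(comp.tu_fraction, e, mm)
    elif comp.conc is not None:
        c = np.asarray(comp.conc, dtype=float)
        p = c / c.sum()
    else:
        raise ValueError(
            "need mass_fraction, tu_fraction, or conc to determine fractions"
        )
    ec50_mix = mixture_ec50_ca(p, e)
    tu = cm = None
    interaction, independent = Interaction.UNCLASSIFIED, False
    if comp.conc is not None:
        tu = toxic_units(comp.conc, e)
        cm = cm_from_tu(tu, ec50_mix)
        interaction, independent = classify_interaction_tu(tu, tu_band)
    return CAResult(
        ec50_mix=ec50_mix,
        tu=tu,
        c_m=cm,
        conc_range=component_conc_range(p, ec50_mix, tu_band),
        interaction=interaction,
        independent_action=independent,
    )
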