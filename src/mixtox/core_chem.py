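"""Domain types, unit conversions, and EPA toxicity labelling.

Potency values always carry an explicit unit; conversions between scales
(pEC50 <-> mol/L <-> mg/L) are explicit operations, never silent coercions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd


class Endpoint(str, enum.Enum):
    EC50 = "EC50"
    LC50 = "LC50"
    LD50 = "LD50"
    pEC50 = "pEC50"
    pLC50 = "pLC50"


class Unit(str, enum.Enum):
    MOL_PER_L = "mol_per_L"
    MG_PER_L = "mg_per_L"
    G_PER_L = "g_per_L"
    MG_PER_KG = "mg_per_kg"
    DIMENSIONLESS = "dimensionless"


_P_ENDPOINTS = {Endpoint.pEC50, Endpoint.pLC50}


@dataclass(frozen=True)
class PotencyMeasurement:
    """A single median-effect potency (EC50/LC50/LD50 or its -log10 form)."""

    endpoint: Endpoint
    value: float
    unit: Unit
    context: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"potency value must be finite, got {self.value}")
        if self.endpoint in _P_ENDPOINTS:
            if self.unit is not Unit.DIMENSIONLESS:
                raise ValueError(
                    f"{self.endpoint.value} is dimensionless, got unit {self.unit.value}"
                )
        elif self.value <= 0:
            raise ValueError(
                f"{self.endpoint.value} must be positive, got {self.value}"
            )


@dataclass
class ChemicalRecord:
    """One chemical: identifier, structure, molar mass, and potencies.

    CASRN is stored verbatim and never validated against a registry.
    """

    chem_id: str
    name: str = ""
    casrn: str | None = None
    smiles: str = ""
    molar_mass: float | None = None
    potencies: list[PotencyMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.molar_mass is not None and self.molar_mass <= 0:
            raise ValueError(f"molar_mass must be > 0, got {self.molar_mass}")


class BinaryRule(str, enum.Enum):
    """Which regulatory cutoff defines 'toxic' for a binary label."""

    EC50_LC50_100_MGL = "EC50_LC50_100_mgL"
    LD50_500_MGKG = "LD50_500_mgkg"
    LD50_CUSTOM = "LD50_custom_threshold"


#: LD50 thresholds (mg/kg) supported for the custom rule.
CUSTOM_LD50_THRESHOLDS = (50.0, 250.0, 500.0, 750.0, 1500.0)

_RULE_UNIT = {
    BinaryRule.EC50_LC50_100_MGL: Unit.MG_PER_L,
    BinaryRule.LD50_500_MGKG: Unit.MG_PER_KG,
    BinaryRule.LD50_CUSTOM: Unit.MG_PER_KG,
}


@dataclass(frozen=True)
class ToxicityLabel:
    binary: int
    rule: BinaryRule
    threshold: float

    def __post_init__(self) -> None:
        if self.binary not in (0, 1):
            raise ValueError(f"binary label must be 0 or 1, got {self.binary}")
        if self.threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")


#: EPA acute-toxicity category names, index 0 (benign) .. 4 (worst).
EPA_CLASS_NAMES = (
    "practically nontoxic",
    "slightly toxic",
    "moderately toxic",
    "highly toxic",
    "very highly toxic",
)


@dataclass(frozen=True)
class ToxicityClass:
    class_index: int

    def __post_init__(self) -> None:
        if self.class_index not in range(5):
            raise ValueError(f"class_index must be 0..4, got {self.class_index}")

    @property
    def class_name(self) -> str:
        return EPA_CLASS_NAMES[self.class_index]


def pec50_to_ec50(p: float) -> float:
    """Convert a pEC50/pLC50 (dimensionless) to the EC50 in mol/L.

    EC50 = 10**(-pEC50); strictly decreasing in p.
    """
    if not math.isfinite(p):
        raise ValueError(f"pEC50 must be finite, got {p}")
    return 10.0 ** (-p)


def ec50_to_pec50(ec50_mol_L: float) -> float:
    """Inverse of :func:`pec50_to_ec50` (-log10 of a mol/L potency)."""
    if not (ec50_mol_L > 0 and math.isfinite(ec50_mol_L)):
        raise ValueError(f"EC50 must be positive and finite, got {ec50_mol_L}")
    return -math.log10(ec50_mol_L)


def molar_to_mass_conc(
    ec50_mol_L: float,
    components: Sequence[tuple[float, float]],
) -> float:
    """Convert a mixture EC50 from mol/L to g/L.

    ``components`` is a sequence of (molar_mass g/mol, mole_fraction) pairs;
    the result is ec50 x sum(molar_mass_i * mole_fraction_i), i.e. the molar
    potency scaled by the mole-fraction-weighted mean molecular weight.
    """
    if ec50_mol_L <= 0 or not math.isfinite(ec50_mol_L):
        raise ValueError(f"EC50 must be positive and finite, got {ec50_mol_L}")
    if not components:
        raise ValueError("at least one component required")
    fracs = [f for _, f in components]
    if any(f < 0 for f in fracs):
        raise ValueError(f"mole fractions must be >= 0, got {fracs}")
    total = sum(fracs)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(
            f"mole fractions must sum to 1 (deviation {total - 1.0:+.3e})"
        )
    if any(m <= 0 for m, _ in components):
        raise ValueError("molar masses must be > 0")
    return ec50_mol_L * sum(m * f for m, f in components)


def label_binary(
    conc: float,
    unit: Unit,
    rule: BinaryRule,
    threshold: float | None = None,
) -> ToxicityLabel:
    """Binary toxic/non-toxic label under a regulatory cutoff rule.

    A concentration strictly below the threshold is toxic; a value exactly at
    the threshold is non-toxic (100 mg/L and 500 mg/kg are non-toxic).
    """
    if conc <= 0 or not math.isfinite(conc):
        raise ValueError(f"concentration must be positive and finite, got {conc}")
    expected_unit = _RULE_UNIT[rule]
    if unit is not expected_unit:
        raise ValueError(
            f"rule {rule.value} expects unit {expected_unit.value}, got {unit.value}"
        )
    if rule is BinaryRule.EC50_LC50_100_MGL:
        cutoff = 100.0
    elif rule is BinaryRule.LD50_500_MGKG:
        cutoff = 500.0
    else:
        if threshold is None:
            raise ValueError("LD50_custom_threshold requires an explicit threshold")
        if threshold not in CUSTOM_LD50_THRESHOLDS:
            raise ValueError(
                f"custom LD50 threshold must be one of {CUSTOM_LD50_THRESHOLDS}, "
                f"got {threshold}"
            )
        cutoff = float(threshold)
    return ToxicityLabel(binary=int(conc < cutoff), rule=rule, threshold=cutoff)


def epa_class(conc_mg_L: float) -> ToxicityClass:
    """Map a mg/L potency onto the EPA 5-category acute-toxicity scale.

    Bands: <0.1 -> 4 (very highly toxic); [0.1, 1] -> 3; (1, 10] -> 2;
    (10, 100] -> 1; >100 -> 0 (practically nontoxic). The printed bands are
    half-open, closed at the listed upper bound, so every positive
    concentration gets exactly one class.
    """
    if conc_mg_L <= 0 or not math.isfinite(conc_mg_L):
        raise ValueError(f"concentration must be positive and finite, got {conc_mg_L}")
    if conc_mg_L < 0.1:
        return ToxicityClass(4)
    if conc_mg_L <= 1.0:
        return ToxicityClass(3)
    if conc_mg_L <= 10.0:
        return ToxicityClass(2)
    if conc_mg_L <= 100.0:
        return ToxicityClass(1)
    return ToxicityClass(0)


# ---------------------------------------------------------------------------
# CSV interchange

CHEMICAL_CSV_COLUMNS = [
    "chem_id", "name", "casrn", "smiles", "molar_mass", "endpoint", "value", "unit",
]


def read_chemicals_csv(path) -> list[ChemicalRecord]:
    """Read a long-format chemical table (one row per potency measurement)."""
    df = pd.read_csv(path, dtype={"chem_id": str, "casrn": str})
    records: dict[str, ChemicalRecord] = {}
    for _, row in df.iterrows():
        cid = str(row["chem_id"])
        if cid not in records:
            mm = row.get("molar_mass")
            records[cid] = ChemicalRecord(
                chem_id=cid,
                name=str(row.get("name", "") or ""),
                casrn=None if pd.isna(row.get("casrn")) else str(row["casrn"]),
                smiles=str(row.get("smiles", "") or ""),
                molar_mass=None if pd.isna(mm) else float(mm),
            )
        if "endpoint" in row and not pd.isna(row["endpoint"]):
            records[cid].potencies.append(
                PotencyMeasurement(
                    endpoint=Endpoint(row["endpoint"]),
                    value=float(row["value"]),
                    unit=Unit(row["unit"]),
                )
            )
    return list(records.values())


def write_chemicals_csv(records: Iterable[ChemicalRecord], path) -> None:
    rows = []
    for rec in records:
        base = {
            "chem_id": rec.chem_id,
            "name": rec.name,
            "casrn": rec.casrn,
            "smiles": rec.smiles,
            "molar_mass": rec.molar_mass,
        }
        if rec.potencies:
            for p in rec.potencies:
                rows.append({**base, "endpoint": p.endpoint.value,
                             "value": p.value, "unit": p.unit.value})
        else:
            rows.append({**base, "endpoint": None, "value": None, "unit": None})
    pd.DataFrame(rows, columns=CHEMICAL_CSV_COLUMNS).to_csv(path, index=False)
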