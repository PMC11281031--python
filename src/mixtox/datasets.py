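"""Packaged reference tables used by the validation examples and tests."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_validation_chemicals",
    "load_pfas_single_toxicity",
    "load_pfas_mixture_ld50",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("mixtox.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_validation_chemicals() -> pd.DataFrame:
    """The eleven chemicals (name, CASRN) used for the zebrafish binary
    combinations."""
    return _read("chemicals_table.csv")


def load_pfas_single_toxicity() -> pd.DataFrame:
    """Zebrafish-embryo LD50/EC50 (uM) of PFOS and PFOA acting alone."""
    return _read("pfas_single_toxicity.csv")


def load_pfas_mixture_ld50() -> pd.DataFrame:
    """PFOA LD50 (uM) at three fixed background PFOS concentrations."""
    return _read("pfas_mixture_ld50.csv")
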