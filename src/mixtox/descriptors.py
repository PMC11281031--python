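"""Pluggable per-chemical descriptor backends.

The pipeline consumes a chemicals x descriptors DataFrame from any backend.
Two are provided: an RDKit backend (2D physicochemical descriptors and
Morgan fingerprints for real SMILES) and the synthetic backend in
:mod:`mixtox.synthetic`, whose random-string "SMILES" need no chemistry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["rdkit_descriptors", "rdkit_fingerprints"]


def _require_rdkit():
    try:
        from rdkit import Chem  # noqa: F401
        return Chem
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "the RDKit backend requires the optional dependency rdkit "
            "(pip install mixtox[chem])"
        ) from exc


def rdkit_descriptors(smiles_by_id: dict[str, str]) -> pd.DataFrame:
    """2D descriptor matrix for real SMILES via RDKit.

    Unparsable SMILES yield all-NaN rows (impute downstream); descriptor
    columns are RDKit's full 2D descriptor list.
    """
    Chem = _require_rdkit()
    from rdkit.Chem import Descriptors
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    names = [name for name, _ in Descriptors.descList]
    rows = {}
    for cid, smi in smiles_by_id.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            rows[cid] = [np.nan] * len(names)
            continue
        vals = []
        for _, fn in Descriptors.descList:
            try:
                vals.append(float(fn(mol)))
            except Exception:
                vals.append(np.nan)
        rows[cid] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=names).rename_axis(
        "chem_id"
    )


def rdkit_fingerprints(
    smiles_by_id: dict[str, str],
    n_bits: int = 2048,
    radius: int = 2,
) -> dict[str, np.ndarray]:
    """Morgan (circular, radius 2, 2048-bit by default) fingerprints."""
    Chem = _require_rdkit()
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = {}
    for cid, smi in smiles_by_id.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            out[cid] = np.zeros(n_bits, dtype=np.uint8)
            continue
        fp = gen.GetFingerprint(mol)
        out[cid] = np.array(fp, dtype=np.uint8)
    return out
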