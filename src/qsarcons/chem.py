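"""Optional chemistry adapter (requires RDKit).

Computes circular (Morgan) fingerprints from SMILES and approximate
functional-group membership masks.  The statistical core never imports this
module; all analyses accept precomputed bit matrices, so the package works
end-to-end without a chemistry toolkit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["morgan_fingerprints", "functional_group_masks", "FUNCTIONAL_GROUP_SMARTS"]

#: Approximate SMARTS definitions for nine functional groups commonly
#: profiled in thyroid-disruptor screens.  These are pragmatic patterns, not
#: a curated substructure dictionary; counts obtained with them will differ
#: from any specific annotation tool.
FUNCTIONAL_GROUP_SMARTS = {
    "phenols": "[OX2H][c]",
    "thiophosphoric acid derivatives": "[PX4](=S)",
    "nitro compounds": "[$([NX3](=O)=O),$([NX3+](=O)[O-])]",
    "diarylethers": "[c][OX2][c]",
    "benzyl halides": "[c][CH2][F,Cl,Br,I]",
    "gem-trihalides": "[CX4]([F,Cl,Br,I])([F,Cl,Br,I])[F,Cl,Br,I]",
    "primary aromatic amines": "[NX3H2][c]",
    "aryl halides": "[c][F,Cl,Br,I]",
    "arenes": "c1ccccc1",
}


def _rdkit():
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "the chemistry adapter requires rdkit (install qsarcons[chem])"
        ) from exc
    return Chem, rdFingerprintGenerator


def _mols(smiles_list):
    Chem, _ = _rdkit()
    mols = []
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValidationError(f"unparsable SMILES at position {i}: {smi!r}")
        mols.append(mol)
    return mols


def morgan_fingerprints(smiles_list, radius: int = 2, n_bits: int = 1024) -> pd.DataFrame:
    """Circular fingerprints (default radius 2, 1024 bits) as a 0/1 frame."""
    _, gen_mod = _rdkit()
    gen = gen_mod.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows = np.zeros((len(smiles_list), n_bits), dtype=np.int8)
    for i, mol in enumerate(_mols(smiles_list)):
        fp = gen.GetFingerprint(mol)
        rows[i, list(fp.GetOnBits())] = 1
    return pd.DataFrame(rows, columns=[f"fp_{b:04d}" for b in range(n_bits)])


def functional_group_masks(smiles_list, patterns=None) -> dict[str, np.ndarray]:
    """Boolean membership masks per named SMARTS pattern (approximate defaults)."""
    Chem, _ = _rdkit()
    patterns = dict(patterns or FUNCTIONAL_GROUP_SMARTS)
    queries = {}
    for name, smarts in patterns.items():
        q = Chem.MolFromSmarts(smarts)
        if q is None:
            raise ValidationError(f"invalid SMARTS for group {name!r}: {smarts!r}")
        queries[name] = q
    mols = _mols(smiles_list)
    return {
        name: np.array([mol.HasSubstructMatch(q) for mol in mols], dtype=bool)
        for name, q in queries.items()
    }
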