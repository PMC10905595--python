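"""Substituent descriptor computation from SMILES fragments.

Ten descriptors over the substituent part of a compound: aromatic ring
count (arings), H-bond acceptor/donor counts (acc, don), heavy atom count
(a_heavy), Crippen logP (logp), rotatable bond count (rbc), ring count
(rings), topological polar surface area (tpsa, A^2), van der Waals volume
(vdw_vol, A^3), and molecular weight (mw, Da).

vdw_vol uses the Bondi-sphere sum with the standard bond/ring overlap
correction (V = sum 4/3 pi r^3 - 5.92 N_bonds - 14.7 R_arom - 3.8 R_aliph),
which needs no 3D conformer.  Descriptor values are toolkit-versioned:
logP/TPSA parameterizations drift between releases, so tests pin values
recomputed with the installed toolkit rather than literature constants.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = ["compute_substituent_descriptors"]


def _descriptor_row(mol) -> dict:
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

    ri = mol.GetRingInfo()
    n_rings = rdMolDescriptors.CalcNumRings(mol)
    n_arom = rdMolDescriptors.CalcNumAromaticRings(mol)

    molh = Chem.AddHs(mol)
    pt = Chem.GetPeriodicTable()
    sphere = sum(
        4.0 / 3.0 * math.pi * pt.GetRvdw(a.GetAtomicNum()) ** 3
        for a in molh.GetAtoms()
    )
    vdw_vol = sphere - 5.92 * molh.GetNumBonds() - 14.7 * n_arom - 3.8 * (
        n_rings - n_arom
    )

    return {
        "arings": float(n_arom),
        "acc": float(rdMolDescriptors.CalcNumHBA(mol)),
        "don": float(rdMolDescriptors.CalcNumHBD(mol)),
        "a_heavy": float(mol.GetNumHeavyAtoms()),
        "logp": float(Crippen.MolLogP(mol)),
        "rbc": float(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        "rings": float(n_rings),
        "tpsa": float(rdMolDescriptors.CalcTPSA(mol)),
        "vdw_vol": float(vdw_vol),
        "mw": float(Descriptors.MolWt(mol)),
    }


def compute_substituent_descriptors(structures) -> pd.DataFrame:
    """Compute the ten substituent descriptors for each SMILES fragment.

    Parameters
    ----------
    structures : iterable of str
        SMILES of the substituent fragments (the substituent part is
        supplied directly).

    Returns
    -------
    DataFrame with one row per fragment, columns in the standard
    descriptor order, indexed by the input SMILES.

    Raises
    ------
    ValueError listing every unparseable input string.
    """
    from rdkit import Chem

    structures = list(structures)
    mols = [Chem.MolFromSmiles(s) for s in structures]
    bad = [s for s, m in zip(structures, mols) if m is None]
    if bad:
        raise ValueError(f"unparseable SMILES: {bad}")
    rows = [_descriptor_row(m) for m in mols]
    return pd.DataFrame(rows, index=pd.Index(structures, name="smiles"))
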