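"""Molecular descriptor providers.

The SAR engine is descriptor-agnostic: any deterministic mapping from a
structure to a fixed-length real vector satisfies the provider contract.
The bundled provider computes eight constitutional descriptors from a
SMILES string parsed with RDKit — coarse whole-molecule counts that are
cheap, interpretable and sufficient for the linear ensemble models used
here.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, Lipinski

RDLogger.DisableLog("rdApp.*")  # RDKit warnings go through our own errors

__all__ = ["DescriptorProvider", "ConstitutionalDescriptors", "SmilesParseError"]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@runtime_checkable
class DescriptorProvider(Protocol):
    """Deterministic structure -> descriptor-vector mapping."""

    name: str

    @property
    def dimension(self) -> int: ...

    @property
    def descriptor_names(self) -> tuple[str, ...]: ...

    def __call__(self, smiles: str) -> np.ndarray: ...


class ConstitutionalDescriptors:
    """Eight constitutional descriptors computed from SMILES.

    heavy_atoms, mol_weight (Da), rings, aromatic_atoms, heteroatoms,
    rotatable_bonds, h_donors, h_acceptors.
    """

    name = "constitutional8"

    _NAMES = (
        "heavy_atoms",
        "mol_weight",
        "rings",
        "aromatic_atoms",
        "heteroatoms",
        "rotatable_bonds",
        "h_donors",
        "h_acceptors",
    )

    @property
    def dimension(self) -> int:
        return len(self._NAMES)

    @property
    def descriptor_names(self) -> tuple[str, ...]:
        return self._NAMES

    def __call__(self, smiles: str) -> np.ndarray:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
        aromatic = sum(1 for atom in mol.GetAtoms() if atom.GetIsAromatic())
        hetero = sum(1 for atom in mol.GetAtoms() if atom.GetAtomicNum() not in (1, 6))
        return np.array(
            [
                mol.GetNumHeavyAtoms(),
                Descriptors.MolWt(mol),
                mol.GetRingInfo().NumRings(),
                aromatic,
                hetero,
                Lipinski.NumRotatableBonds(mol),
                Lipinski.NumHDonors(mol),
                Lipinski.NumHAcceptors(mol),
            ],
            dtype=float,
        )
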