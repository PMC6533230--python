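"""Structure backends: pluggable chemistry engines that derive the
transient identifier fields (formula/inchi/inchiKey/smiles) from a
component's Molfile CTAB payload.

The Mixfile format treats the molfile as the primary structure record and
the four identifier fields as derived properties; this module provides the
RDKit implementation of that recalculation. Everything else in the package
treats molfiles as opaque strings, so the import is lazy and the package
works without RDKit installed.
"""

from __future__ import annotations

from .model import StructureProps


class RDKitBackend:
    """Derive identifiers from Molfile CTAB V2000 text using RDKit."""

    def __init__(self) -> None:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import rdMolDescriptors

        RDLogger.DisableLog("rdApp.*")
        self._chem = Chem
        self._descriptors = rdMolDescriptors

    def from_molfile(self, molfile: str) -> StructureProps:
        mol = self._chem.MolFromMolBlock(molfile, sanitize=True)
        if mol is None:
            raise ValueError("molfile could not be interpreted")
        return StructureProps(
            formula=self._descriptors.CalcMolFormula(mol),
            inchi=self._chem.MolToInchi(mol),
            inchiKey=self._chem.MolToInchiKey(mol),
            smiles=self._chem.MolToSmiles(mol),
        )

    def molfile_from_smiles(self, smiles: str) -> str:
        """Convenience for building test documents: SMILES → 2D molfile."""
        from rdkit.Chem import AllChem

        mol = self._chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"bad SMILES {smiles!r}")
        AllChem.Compute2DCoords(mol)
        return self._chem.MolToMolBlock(mol)
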