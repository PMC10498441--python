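"""Molecule identity and elementary molecular measures.

Every compound in the planner is keyed by its canonical SMILES so that
different spellings of the same structure collapse onto a single node of the
synthesis network.  Canonicalization uses RDKit's default canonical SMILES
with stereochemistry retained.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return mol


@lru_cache(maxsize=200_000)
def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES for ``smiles``.

    Idempotent: ``canonicalize(canonicalize(s)) == canonicalize(s)``.
    Multi-fragment inputs (dot-separated) are canonicalized as a whole.

    Raises
    ------
    SmilesParseError
        If the input does not parse.
    """
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def heavy_atoms(smiles: str) -> int:
    """Number of non-hydrogen atoms in the molecule."""
    return _mol_from_smiles(smiles).GetNumHeavyAtoms()


@dataclass(frozen=True)
class Molecule:
    """A compound keyed by canonical SMILES.

    ``price`` is present iff the compound is purchasable (catalog pack price,
    unitless currency).
    """

    smiles: str
    heavy_atom_count: int
    is_purchasable: bool = False
    price: Optional[float] = None

    def __post_init__(self) -> None:
        if self.heavy_atom_count < 1:
            raise ValueError("molecule must have at least one heavy atom")
        if self.is_purchasable:
            if self.price is None or self.price <= 0:
                raise ValueError("purchasable molecule requires a positive price")
        elif self.price is not None:
            raise ValueError("price only allowed on purchasable molecules")

    @classmethod
    def from_smiles(
        cls,
        smiles: str,
        *,
        is_purchasable: bool = False,
        price: Optional[float] = None,
        allow_fragments: bool = False,
    ) -> "Molecule":
        """Build a Molecule from any SMILES spelling.

        Single-molecule inputs only: dot-separated multi-fragment SMILES
        (salts, mixtures) are rejected unless ``allow_fragments`` is set,
        because reaction products in the network are single molecules.
        """
        canon = canonicalize(smiles)
        if not allow_fragments and "." in canon:
            raise SmilesParseError(
                f"multi-fragment SMILES not accepted as a compound: {smiles!r}"
            )
        return cls(
            smiles=canon,
            heavy_atom_count=heavy_atoms(canon),
            is_purchasable=is_purchasable,
            price=price,
        )
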