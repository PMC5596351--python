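"""Molecule standardization and SMILES I/O.

All downstream stages (fragmentation, pair detection, interference
flagging) operate on :class:`Molecule` objects whose ``canonical_smiles``
was produced by a single standardization route: strip to the largest
organic fragment (salt/solvate removal), neutralize charges where
possible, and emit the RDKit canonical SMILES. Exact-structure
comparisons anywhere in the package therefore mean string equality of
``canonical_smiles``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "Molecule",
    "MoleculeError",
    "ParseFailure",
    "canonicalize",
    "canonicalize_library",
    "read_smiles_file",
    "write_smiles_file",
]


class MoleculeError(ValueError):
    """Raised when a SMILES string cannot be parsed or standardized."""


@dataclass(frozen=True, slots=True)
class Molecule:
    """A standardized structure with a stable identifier.

    Attributes
    ----------
    id : str
        Caller-supplied compound identifier.
    smiles : str
        The input SMILES as given.
    canonical_smiles : str
        Canonical SMILES of the largest organic fragment after
        neutralization; idempotent under re-canonicalization.
    n_heavy : int
        Heavy (non-hydrogen) atom count of the standardized structure.
    """

    id: str
    smiles: str
    canonical_smiles: str
    n_heavy: int


@dataclass(frozen=True, slots=True)
class ParseFailure:
    id: str
    smiles: str
    reason: str


_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def _standardize_rdmol(mol: Chem.Mol) -> Chem.Mol:
    mol = _LARGEST_FRAGMENT.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    Chem.SanitizeMol(mol)
    return mol


def canonicalize(smiles: str, id: str) -> Molecule:
    """Parse ``smiles``, strip salts, neutralize, and canonicalize.

    Raises
    ------
    MoleculeError
        If the SMILES cannot be parsed or standardized.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"unparseable SMILES for {id!r}: {smiles!r}")
    try:
        mol = _standardize_rdmol(mol)
    except Exception as exc:  # pragma: no cover - RDKit failure modes vary
        raise MoleculeError(f"standardization failed for {id!r}: {exc}") from exc
    can = Chem.MolToSmiles(mol)
    if not can:
        raise MoleculeError(f"empty structure for {id!r}: {smiles!r}")
    return Molecule(id=id, smiles=smiles, canonical_smiles=can, n_heavy=mol.GetNumHeavyAtoms())


def canonicalize_library(
    records: Iterable[tuple[str, str]],
) -> tuple[list[Molecule], list[ParseFailure]]:
    """Canonicalize ``(smiles, id)`` pairs, skipping unparseable records.

    Failures are collected (and logged) rather than raised so that a
    large library import survives isolated bad records.
    """
    molecules: list[Molecule] = []
    failures: list[ParseFailure] = []
    for smiles, mol_id in records:
        try:
            molecules.append(canonicalize(smiles, mol_id))
        except MoleculeError as exc:
            logger.warning("skipping %s: %s", mol_id, exc)
            failures.append(ParseFailure(id=mol_id, smiles=smiles, reason=str(exc)))
    return molecules, failures


def read_smiles_file(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(smiles, id)`` from a whitespace-delimited SMILES file.

    One record per line: SMILES, whitespace, identifier. Blank lines and
    ``#`` comments are ignored; a record without an identifier gets a
    positional one.
    """
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"MOL{i}"
            yield smiles, mol_id


def write_smiles_file(path: str | Path, molecules: Iterable[Molecule]) -> None:
    with open(path, "w") as fh:
        for mol in molecules:
            fh.write(f"{mol.canonical_smiles} {mol.id}\n")
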