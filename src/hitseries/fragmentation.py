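"""Single-cut fragmentation of exocyclic single bonds.

A matched molecular pair rests on a single-cut decomposition: one
acyclic single bond between heavy atoms is broken, yielding a *core*
and a *substituent*, each carrying one labeled attachment point
(``[*]``). Two rule sets control which bonds may be cut:

``"exocyclic"``
    every acyclic single bond between two heavy atoms — the most
    permissive single-cut scheme, convenient for transparent tests;

``"recap"`` (default)
    only bonds of classical retrosynthetic (RECAP-style) types: amide,
    ester, aliphatic amine, urea, ether, sulfonamide, aromatic
    nitrogen-aliphatic carbon, lactam nitrogen-aliphatic carbon, and
    biaryl carbon-carbon bonds.

Cuts are filtered by size restrictions that confine the varying part to
substituent-sized fragments: the substituent must have at most
``max_sub_heavy`` heavy atoms and the core at least
``min_core_to_sub_ratio`` times as many as the substituent. The
thresholds shipped as defaults (13 heavy atoms, ratio 2, pairwise
difference 8) follow common practice in the matched-molecular-pair
literature and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from rdkit import Chem

from .chem import Molecule

__all__ = [
    "SizeRestrictions",
    "FragmentCut",
    "RULE_SETS",
    "fragment_single_cuts",
]


@dataclass(frozen=True, slots=True)
class SizeRestrictions:
    """Transformation size limits for single-cut fragmentation.

    max_sub_heavy:
        largest allowed substituent, in heavy atoms.
    max_sub_difference_heavy:
        largest allowed heavy-atom difference between the two exchanged
        substituents of a pair.
    min_core_to_sub_ratio:
        the core must have at least this many times the substituent's
        heavy atoms.
    """

    max_sub_heavy: int = 13
    max_sub_difference_heavy: int = 8
    min_core_to_sub_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.max_sub_heavy <= 0 or self.max_sub_difference_heavy <= 0:
            raise ValueError("size restrictions must be positive")
        if self.min_core_to_sub_ratio <= 0:
            raise ValueError("min_core_to_sub_ratio must be positive")


@dataclass(frozen=True, slots=True)
class FragmentCut:
    """One oriented single-bond cut: parent = core + substituent."""

    molecule_id: str
    core: str
    substituent: str
    core_heavy: int
    sub_heavy: int


# Each pattern marks one cleavable bond between its first two mapped
# match atoms. Overlapping patterns are harmless: candidate bonds are
# collected into a set before cutting.
_RECAP_BOND_SMARTS: tuple[tuple[str, str], ...] = (
    ("amide", "[C;$(C=O)]!@[N;!$(N=*)]"),
    ("ester", "[C;$(C=O)]!@[OX2;!$([O]=*)]"),
    ("amine", "[C;!$(C=O);!$(C=N);!$(C=S)]!@[NX3;!$(N=*);!$(N[C,S]=[O,S,N])]"),
    ("urea", "[N;$(NC(=O)N)]!@[C;$(C(=O)(N)N)]"),
    ("ether", "[C;!$(C=O)]!@[OX2;!$(OC=O)]"),
    ("sulfonamide", "[S;$(S(=O)=O)]!@[NX3]"),
    ("aromatic_n_aliphatic_c", "[n]!@[C;!$(C=O)]"),
    ("lactam_n_aliphatic_c", "[N;R;$(NC=O)]!@[C;!$(C=O)]"),
    ("biaryl", "[c]!@[c]"),
)

RULE_SETS = ("recap", "exocyclic")


@lru_cache(maxsize=None)
def _recap_queries() -> tuple[tuple[str, Chem.Mol], ...]:
    return tuple((name, Chem.MolFromSmarts(smarts)) for name, smarts in _RECAP_BOND_SMARTS)


def _candidate_bonds(mol: Chem.Mol, rules: str) -> list[int]:
    """Indices of cleavable bonds: single, acyclic, both atoms heavy."""
    eligible: set[int] = set()
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        eligible.add(bond.GetIdx())
    if rules == "exocyclic":
        return sorted(eligible)
    if rules != "recap":
        raise ValueError(f"unknown rule set: {rules!r} (expected one of {RULE_SETS})")
    hits: set[int] = set()
    for _, query in _recap_queries():
        for match in mol.GetSubstructMatches(query):
            bond = mol.GetBondBetweenAtoms(match[0], match[1])
            if bond is not None and bond.GetIdx() in eligible:
                hits.add(bond.GetIdx())
    return sorted(hits)


def _fragment_pair(mol: Chem.Mol, bond_idx: int) -> tuple[tuple[str, int], tuple[str, int]] | None:
    """Cut one acyclic bond; return ((smiles, n_heavy), (smiles, n_heavy))."""
    cut = Chem.FragmentOnBonds(mol, [bond_idx], addDummies=True, dummyLabels=[(0, 0)])
    try:
        frags = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)
    except Exception:
        return None
    if len(frags) != 2:
        return None
    out = []
    for frag in frags:
        # dummy atoms (atomic number 0) are not counted as heavy atoms
        out.append((Chem.MolToSmiles(frag), frag.GetNumHeavyAtoms()))
    return out[0], out[1]


def fragment_single_cuts(
    mol: Molecule,
    rules: str = "recap",
    restrictions: SizeRestrictions | None = None,
) -> list[FragmentCut]:
    """Enumerate all admissible single-cut (core, substituent) splits.

    Both orientations of every cleavable bond are considered; a cut is
    kept when the substituent has at least one heavy atom, at most
    ``max_sub_heavy``, and the core is at least ``min_core_to_sub_ratio``
    times larger. Output is deduplicated and sorted, so it is
    deterministic for a given structure.
    """
    restrictions = restrictions or SizeRestrictions()
    rdmol = Chem.MolFromSmiles(mol.canonical_smiles)
    if rdmol is None:
        raise ValueError(f"molecule {mol.id!r} has an invalid canonical SMILES")
    cuts: set[tuple[str, str, int, int]] = set()
    for bond_idx in _candidate_bonds(rdmol, rules):
        pair = _fragment_pair(rdmol, bond_idx)
        if pair is None:
            continue
        for (core, core_heavy), (sub, sub_heavy) in (pair, pair[::-1]):
            if sub_heavy < 1:
                continue
            if sub_heavy > restrictions.max_sub_heavy:
                continue
            if core_heavy < restrictions.min_core_to_sub_ratio * sub_heavy:
                continue
            cuts.add((core, sub, core_heavy, sub_heavy))
    return [
        FragmentCut(mol.id, core, sub, core_heavy, sub_heavy)
        for core, sub, core_heavy, sub_heavy in sorted(cuts)
    ]
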