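"""PAINS substructure and aggregator flagging of series members.

Two orthogonal interference signals are attached to each compound:

* **PAINS** — pan-assay interference substructure classes; a compound
  is flagged with every family whose pattern matches as a substructure
  of the standardized structure (no match-count threshold).
* **aggregator** — exact identity (canonical SMILES equality after
  salt stripping and charge normalization) with an entry of a known
  colloidal-aggregator reference list.

The PAINS catalog is an input, not a hard-wired table: the A/B/C family
dialects differ between filter distributions, so users load the catalog
they trust. :func:`reference_pains_catalog` exposes the 480-family
catalog shipped with RDKit's filter collection for convenience.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit.Chem import FilterCatalog as _FC

from .chem import Molecule, canonicalize
from .mms import MMS

__all__ = [
    "PainsCatalog",
    "InterferenceFlags",
    "FlagCensus",
    "load_pains",
    "reference_pains_catalog",
    "load_aggregators",
    "flag_compound",
    "flag_library",
    "census",
]


class PainsCatalog:
    """A compiled catalog of (family, substructure pattern) entries."""

    def __init__(self, entries: Sequence[tuple[str, str]]):
        self._entries: list[tuple[str, Chem.Mol, str]] = []
        seen: set[tuple[str, str]] = set()
        for family, smarts in entries:
            if (family, smarts) in seen:
                continue
            seen.add((family, smarts))
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                raise ValueError(f"pattern for family {family!r} does not compile: {smarts!r}")
            self._entries.append((family, query, smarts))

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def families(self) -> list[str]:
        return [family for family, _, _ in self._entries]

    def match(self, rdmol: Chem.Mol) -> list[str]:
        """All families whose pattern matches ``rdmol`` as a substructure."""
        return sorted({f for f, q, _ in self._entries if rdmol.HasSubstructMatch(q)})


class _RDKitPainsCatalog(PainsCatalog):
    """Adapter over RDKit's built-in PAINS filter collection."""

    def __init__(self) -> None:
        params = _FC.FilterCatalogParams()
        params.AddCatalog(_FC.FilterCatalogParams.FilterCatalogs.PAINS)
        self._catalog = _FC.FilterCatalog(params)

    def __len__(self) -> int:
        return self._catalog.GetNumEntries()

    @property
    def families(self) -> list[str]:
        return [
            self._catalog.GetEntryWithIdx(i).GetDescription() for i in range(len(self))
        ]

    def match(self, rdmol: Chem.Mol) -> list[str]:
        return sorted({e.GetDescription() for e in self._catalog.GetMatches(rdmol)})


@dataclass(frozen=True, slots=True)
class InterferenceFlags:
    compound_id: str
    pains_families: tuple[str, ...]
    is_aggregator: bool

    @property
    def has_pains(self) -> bool:
        return bool(self.pains_families)


@dataclass(frozen=True, slots=True)
class FlagCensus:
    """Series-level interference counts.

    The identity ``with_aggregator + with_pains - with_both + clean ==
    total`` holds by inclusion-exclusion.
    """

    n_mms_with_aggregator: int
    n_mms_with_pains: int
    n_mms_with_both: int
    n_mms_clean: int

    @property
    def total(self) -> int:
        return (
            self.n_mms_with_aggregator
            + self.n_mms_with_pains
            - self.n_mms_with_both
            + self.n_mms_clean
        )


def load_pains(path: str | Path) -> PainsCatalog:
    """Load a delimited PAINS catalog: one ``pattern<TAB>family`` per line.

    Blank lines and ``#`` comments are skipped; a pattern that does not
    compile raises an error naming its family.
    """
    entries: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split(None, 1)
            if len(parts) < 2:
                raise ValueError(f"catalog line needs pattern and family: {line!r}")
            entries.append((parts[1].strip(), parts[0].strip()))
    return PainsCatalog(entries)


def reference_pains_catalog() -> PainsCatalog:
    """The 480-family PAINS catalog from RDKit's filter collection."""
    return _RDKitPainsCatalog()


def load_aggregators(path: str | Path) -> frozenset[str]:
    """Canonical structures of an aggregator SMILES reference list.

    Entries are standardized with the same salt-strip/neutralize route
    as library compounds, so the 100%-identity comparison is exact.
    """
    from .chem import read_smiles_file

    canon: set[str] = set()
    for smiles, agg_id in read_smiles_file(path):
        canon.add(canonicalize(smiles, agg_id).canonical_smiles)
    return frozenset(canon)


def flag_compound(
    mol: Molecule,
    catalog: PainsCatalog | None = None,
    aggregators: frozenset[str] | set[str] = frozenset(),
) -> InterferenceFlags:
    """Flag one standardized compound against catalog and aggregator list."""
    families: tuple[str, ...] = ()
    if catalog is not None and len(catalog) > 0:
        rdmol = Chem.MolFromSmiles(mol.canonical_smiles)
        if rdmol is None:
            raise ValueError(f"molecule {mol.id!r} has an invalid canonical SMILES")
        families = tuple(catalog.match(rdmol))
    return InterferenceFlags(
        compound_id=mol.id,
        pains_families=families,
        is_aggregator=mol.canonical_smiles in aggregators,
    )


def flag_library(
    mols: Iterable[Molecule],
    catalog: PainsCatalog | None = None,
    aggregators: frozenset[str] | set[str] = frozenset(),
) -> dict[str, InterferenceFlags]:
    return {m.id: flag_compound(m, catalog, aggregators) for m in mols}


def census(series: Sequence[MMS], flags: Mapping[str, InterferenceFlags]) -> FlagCensus:
    """Count series containing aggregators, PAINS matches, both, or neither.

    A series is aggregator-flagged when at least one member is an
    aggregator, and PAINS-flagged when at least one member matches at
    least one family.
    """
    n_agg = n_pains = n_both = n_clean = 0
    for s in series:
        missing = [m for m in s.sorted_members() if m not in flags]
        if missing:
            raise KeyError(f"missing interference flags for members: {missing}")
        has_agg = any(flags[m].is_aggregator for m in s.members)
        has_pains = any(flags[m].has_pains for m in s.members)
        n_agg += has_agg
        n_pains += has_pains
        n_both += has_agg and has_pains
        n_clean += not has_agg and not has_pains
    return FlagCensus(
        n_mms_with_aggregator=n_agg,
        n_mms_with_pains=n_pains,
        n_mms_with_both=n_both,
        n_mms_clean=n_clean,
    )
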