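"""Matched molecular pairs (MMPs) and matched molecular series (MMSs).

An MMP is a pair of compounds distinguished only by a chemical change
at a single site: both share a single-cut core and differ in the
substituent attached at the core's labeled attachment point. An MMS is
the union of all compounds forming MMPs on the same core — an analog
series varied at exactly one position. Detection is index-based: every
molecule's admissible cuts are grouped by canonical core string, so
candidate pairs are only ever drawn from molecules sharing a core.

Series whose member pairs violate the pairwise substituent-size
restriction are split into maximal cliques of the compliant-pair graph,
so that in every emitted series each member pair is itself a valid MMP.
Redundant series (strict member subsets of a larger series, or
duplicate member sets represented by a smaller core) are removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from rdkit import Chem

from .chem import Molecule
from .fragmentation import FragmentCut, SizeRestrictions, fragment_single_cuts

__all__ = [
    "MMP",
    "MMS",
    "find_mmps",
    "find_mmps_bruteforce",
    "build_mms",
    "remove_redundant",
    "core_heavy_atoms",
    "write_mms_json",
    "read_mms_json",
]


@dataclass(frozen=True, slots=True)
class MMP:
    """An unordered pair of analogs on a shared single-cut core.

    ``compound_a`` < ``compound_b`` lexicographically, so each pair has
    one canonical representation per core.
    """

    compound_a: str
    compound_b: str
    core: str
    sub_a: str
    sub_b: str

    def __post_init__(self) -> None:
        if self.compound_a >= self.compound_b:
            raise ValueError("MMP requires compound_a < compound_b")
        if self.sub_a == self.sub_b:
            raise ValueError("MMP substituents must differ")


@dataclass(frozen=True)
class MMS:
    """An analog series: one core, >= 2 members with distinct substituents."""

    core: str
    members: frozenset[str]
    substituents: dict[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an MMS needs at least two members")
        subs = list(self.substituents.values())
        if len(set(subs)) != len(subs):
            raise ValueError("MMS substituents must be pairwise distinct")

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


def core_heavy_atoms(core: str) -> int:
    """Heavy-atom count of a core fragment (attachment point excluded)."""
    mol = Chem.MolFromSmiles(core)
    if mol is None:
        raise ValueError(f"invalid core fragment: {core!r}")
    return mol.GetNumHeavyAtoms()


# -- MMP detection ----------------------------------------------------------


def _cut_index(
    mols: Sequence[Molecule], rules: str, restrictions: SizeRestrictions
) -> dict[str, list[tuple[str, str, int]]]:
    """core -> sorted list of (molecule_id, substituent, sub_heavy)."""
    index: dict[str, set[tuple[str, str, int]]] = {}
    for mol in mols:
        for cut in fragment_single_cuts(mol, rules, restrictions):
            index.setdefault(cut.core, set()).add((mol.id, cut.substituent, cut.sub_heavy))
    return {core: sorted(entries) for core, entries in index.items()}


def find_mmps(
    mols: Sequence[Molecule],
    rules: str = "recap",
    restrictions: SizeRestrictions | None = None,
) -> list[MMP]:
    """Detect all MMPs in a library via the shared-core cut index.

    Two molecules form an MMP on a core when both produce that core
    with different substituents whose heavy-atom counts differ by at
    most ``max_sub_difference_heavy``. One MMP is emitted per
    (core, pair); output order is deterministic.
    """
    ids = [m.id for m in mols]
    if len(set(ids)) != len(ids):
        raise ValueError("molecule ids must be unique")
    restrictions = restrictions or SizeRestrictions()
    mmps: set[MMP] = set()
    for core, entries in _cut_index(mols, rules, restrictions).items():
        for i in range(len(entries)):
            id_i, sub_i, h_i = entries[i]
            for j in range(i + 1, len(entries)):
                id_j, sub_j, h_j = entries[j]
                if id_i == id_j or sub_i == sub_j:
                    continue
                if abs(h_i - h_j) > restrictions.max_sub_difference_heavy:
                    continue
                a, b = sorted((id_i, id_j))
                sub_a, sub_b = (sub_i, sub_j) if a == id_i else (sub_j, sub_i)
                mmps.add(MMP(compound_a=a, compound_b=b, core=core, sub_a=sub_a, sub_b=sub_b))
    return sorted(mmps, key=lambda p: (p.core, p.compound_a, p.compound_b, p.sub_a, p.sub_b))


def find_mmps_bruteforce(
    mols: Sequence[Molecule],
    rules: str = "recap",
    restrictions: SizeRestrictions | None = None,
) -> list[MMP]:
    """Reference MMP detection without the core index.

    Enumerates all cuts of every pair of molecules directly and keeps
    pairs sharing a core with admissible substituents. Quadratic in the
    library size; used as an independent check of :func:`find_mmps` on
    small libraries.
    """
    restrictions = restrictions or SizeRestrictions()
    cuts: dict[str, list[FragmentCut]] = {
        m.id: fragment_single_cuts(m, rules, restrictions) for m in mols
    }
    mmps: set[MMP] = set()
    ordered = sorted(cuts)
    for i, id_a in enumerate(ordered):
        for id_b in ordered[i + 1 :]:
            for ca in cuts[id_a]:
                for cb in cuts[id_b]:
                    if ca.core != cb.core or ca.substituent == cb.substituent:
                        continue
                    if abs(ca.sub_heavy - cb.sub_heavy) > restrictions.max_sub_difference_heavy:
                        continue
                    mmps.add(
                        MMP(
                            compound_a=id_a,
                            compound_b=id_b,
                            core=ca.core,
                            sub_a=ca.substituent,
                            sub_b=cb.substituent,
                        )
                    )
    return sorted(mmps, key=lambda p: (p.core, p.compound_a, p.compound_b, p.sub_a, p.sub_b))


# -- MMS assembly ------------------------------------------------------------


def build_mms(mmps: Iterable[MMP]) -> list[MMS]:
    """Assemble series by grouping MMPs on their shared core.

    For each core, the MMP relation defines a graph over compounds; an
    MMS must be a set in which *every* member pair is an MMP, i.e. a
    clique. When the graph is complete the whole component is one
    series; otherwise (pairwise size-difference violations) the series
    is split into all maximal cliques of size >= 2, ordered largest
    first with a lexicographic member tie-break.
    """
    by_core: dict[str, list[MMP]] = {}
    for mmp in mmps:
        by_core.setdefault(mmp.core, []).append(mmp)

    series: list[MMS] = []
    for core in sorted(by_core):
        graph = nx.Graph()
        subs: dict[str, str] = {}
        for mmp in by_core[core]:
            graph.add_edge(mmp.compound_a, mmp.compound_b)
            # per (core, member) the substituent is unique by construction
            subs[mmp.compound_a] = mmp.sub_a
            subs[mmp.compound_b] = mmp.sub_b
        cliques = [sorted(c) for c in nx.find_cliques(graph) if len(c) >= 2]
        cliques.sort(key=lambda c: (-len(c), c))
        for members in cliques:
            series.append(
                MMS(
                    core=core,
                    members=frozenset(members),
                    substituents={m: subs[m] for m in members},
                )
            )
    return series


def remove_redundant(series: Sequence[MMS]) -> list[MMS]:
    """Drop redundant series.

    A series is redundant if its member set is a strict subset of
    another's, or if another series has the identical member set but a
    larger core (more heavy atoms). Ties on core size break
    lexicographically on the core string, so the result is
    deterministic.
    """
    # duplicate member sets: keep the largest core
    best: dict[frozenset[str], MMS] = {}
    for s in series:
        cur = best.get(s.members)
        if cur is None:
            best[s.members] = s
            continue
        key_new = (core_heavy_atoms(s.core), s.core)
        key_cur = (core_heavy_atoms(cur.core), cur.core)
        # larger core wins; on equal size the lexicographically smaller
        # core string is kept for determinism
        if key_new[0] > key_cur[0] or (key_new[0] == key_cur[0] and key_new[1] < key_cur[1]):
            best[s.members] = s

    survivors = sorted(best.values(), key=lambda s: (-s.size, sorted(s.members), s.core))
    kept: list[MMS] = []
    for s in survivors:
        if any(s.members < other.members for other in survivors if other is not s):
            continue
        kept.append(s)
    return sorted(kept, key=lambda s: (s.core, sorted(s.members)))


# -- serialization ------------------------------------------------------------


def write_mms_json(path: str | Path, series: Sequence[MMS]) -> None:
    payload = [
        {
            "core": s.core,
            "members": s.sorted_members(),
            "substituents": {m: s.substituents[m] for m in s.sorted_members()},
        }
        for s in series
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_mms_json(path: str | Path) -> list[MMS]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        MMS(core=e["core"], members=frozenset(e["members"]), substituents=dict(e["substituents"]))
        for e in payload
    ]
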