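"""Synthetic screening libraries and activity matrices with known truth.

The generator emulates the statistical shape of a large public
screening corpus so every downstream stage can be exercised and
validated without any download:

* a structure library containing *planted analog series* — a scaffold
  with a single attachment site combined with distinct substituents —
  plus structurally unrelated decoys;
* a compound-assay activity matrix in which each compound is tested in
  a heavy-tailed number of primary assays (hundreds on average, almost
  all above 50), with a sub-percent background hit rate and a planted
  promiscuous tail at a much higher rate;
* partial tested-assay overlap between series members, tunable from
  disjoint to identical.

Decoys are drawn from an enumerated pool of fused aromatic ring systems
with no acyclic single bonds, so they admit no single-cut fragmentation
at all: they can never share a core with a planted series (or with each
other), which makes planted-series recovery exactly checkable.

Everything is driven by explicit seeds; identical configuration and
seed give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .activity import ActivityRecord
from .chem import Molecule, canonicalize

__all__ = [
    "SCAFFOLDS",
    "RING_SCAFFOLDS",
    "SUBSTITUENTS",
    "SeriesPlan",
    "FrequencyLaw",
    "ActivitySimConfig",
    "GroundTruth",
    "ConfigurationError",
    "generate_library",
    "generate_activity",
    "decoy_pool",
    "write_ground_truth",
    "read_ground_truth",
]


class ConfigurationError(ValueError):
    """An identifier in a plan or config does not resolve."""


# Fixed fragment vocabulary (attachment point = atom-mapped dummy).
# Scaffolds are drug-like ring systems of 7-11 heavy atoms with exactly
# one substitution site; substituents are 1-4 heavy atoms, well inside
# the default transformation size restrictions.
SCAFFOLDS: dict[str, str] = {
    "benzamide": "NC(=O)c1ccc(cc1)[*:1]",
    "benzenesulfonamide": "NS(=O)(=O)c1ccc(cc1)[*:1]",
    "acetanilide": "CC(=O)Nc1ccc(cc1)[*:1]",
    "benzonitrile": "N#Cc1ccc(cc1)[*:1]",
    "anisole": "COc1ccc(cc1)[*:1]",
    "biphenyl": "c1ccc(-c2ccc(cc2)[*:1])cc1",
    "naphthalen2yl": "[*:1]c1ccc2ccccc2c1",
    "quinolin2yl": "[*:1]c1ccc2ccccc2n1",
    "indol2yl": "[*:1]c1cc2ccccc2[nH]1",
    "benzimidazol2yl": "[*:1]c1nc2ccccc2[nH]1",
    "benzoxazol2yl": "[*:1]c1nc2ccccc2o1",
    "benzothiazol2yl": "[*:1]c1nc2ccccc2s1",
    "indazol3yl": "[*:1]c1n[nH]c2ccccc12",
    "benzofuran2yl": "[*:1]c1cc2ccccc2o1",
    "benzothiophen2yl": "[*:1]c1cc2ccccc2s1",
    "quinoxalin2yl": "[*:1]c1cnc2ccccc2n1",
    "coumarin3yl": "[*:1]C1=Cc2ccccc2OC1=O",
    "tetralin2yl": "[*:1]C1CCc2ccccc2C1",
    "phenylpiperazine": "c1ccc(N2CCN(CC2)[*:1])cc1",
    "morpholinophenyl": "C1COCCN1c1ccc(cc1)[*:1]",
    "naphthalen1yl": "[*:1]c1cccc2ccccc12",
    "isoquinolin1yl": "[*:1]c1nccc2ccccc12",
    "isoquinolin3yl": "[*:1]c1cc2ccccc2cn1",
    "quinolin3yl": "[*:1]c1cnc2ccccc2c1",
    "quinolin6yl": "[*:1]c1ccc2ncccc2c1",
    "indol5yl": "[*:1]c1ccc2[nH]ccc2c1",
    "benzofuran5yl": "[*:1]c1ccc2occc2c1",
    "benzothiophen5yl": "[*:1]c1ccc2sccc2c1",
    "benzimidazol5yl": "[*:1]c1ccc2[nH]cnc2c1",
}

# Scaffolds whose attachment point sits directly on a fused ring system
# with no exocyclic single bond of their own: two plans built on two
# different entries of this list can never share a single-cut core, so
# planted series are recoverable exactly. The phenylene-linker scaffolds
# above (benzamide, anisole, ...) may legitimately share cores with
# other plans when a substituent recreates another scaffold's fixed
# group - realistic, but not what a recovery experiment wants.
RING_SCAFFOLDS: tuple[str, ...] = (
    "naphthalen2yl",
    "naphthalen1yl",
    "quinolin2yl",
    "quinolin3yl",
    "quinolin6yl",
    "isoquinolin1yl",
    "isoquinolin3yl",
    "indol2yl",
    "indol5yl",
    "benzimidazol2yl",
    "benzimidazol5yl",
    "benzoxazol2yl",
    "benzothiazol2yl",
    "indazol3yl",
    "benzofuran2yl",
    "benzofuran5yl",
    "benzothiophen2yl",
    "benzothiophen5yl",
    "quinoxalin2yl",
    "coumarin3yl",
    "tetralin2yl",
)

SUBSTITUENTS: dict[str, str] = {
    "methyl": "[*:1]C",
    "ethyl": "[*:1]CC",
    "propyl": "[*:1]CCC",
    "isopropyl": "[*:1]C(C)C",
    "butyl": "[*:1]CCCC",
    "tert_butyl": "[*:1]C(C)(C)C",
    "fluoro": "[*:1]F",
    "chloro": "[*:1]Cl",
    "bromo": "[*:1]Br",
    "iodo": "[*:1]I",
    "hydroxy": "[*:1]O",
    "methoxy": "[*:1]OC",
    "ethoxy": "[*:1]OCC",
    "isopropoxy": "[*:1]OC(C)C",
    "amino": "[*:1]N",
    "methylamino": "[*:1]NC",
    "dimethylamino": "[*:1]N(C)C",
    "cyano": "[*:1]C#N",
    "trifluoromethyl": "[*:1]C(F)(F)F",
    "vinyl": "[*:1]C=C",
    "acetyl": "[*:1]C(=O)C",
    "carbamoyl": "[*:1]C(=O)N",
    "carboxy": "[*:1]C(=O)O",
    "methoxycarbonyl": "[*:1]C(=O)OC",
    "sulfanyl": "[*:1]S",
    "methylthio": "[*:1]SC",
    "nitro": "[*:1][N+](=O)[O-]",
    "hydroxymethyl": "[*:1]CO",
    "cyanomethyl": "[*:1]CC#N",
    "fluoromethyl": "[*:1]CF",
}


@dataclass(frozen=True, slots=True)
class SeriesPlan:
    """Blueprint of one planted analog series.

    One scaffold (single attachment site) combined with >= 2 distinct
    substituents gives one molecule per substituent.
    """

    core_template: str
    substituents: tuple[str, ...]
    site_label: str = "R1"

    def __post_init__(self) -> None:
        if len(self.substituents) < 2:
            raise ValueError("a planted series needs at least two substituents")
        if len(set(self.substituents)) != len(self.substituents):
            raise ValueError("planted substituents must be distinct")

    @property
    def size(self) -> int:
        return len(self.substituents)


@dataclass(frozen=True, slots=True)
class FrequencyLaw:
    """Discretized lognormal law for per-compound assay frequency.

    Draws are rounded and clipped to ``[low, n_assays]``. The defaults
    (median 347, sigma 1.18, floor 50) reproduce the shape of a corpus
    of extensively assayed screening compounds: a median in the
    hundreds with ~95% of compounds above 50 assays.
    """

    median: float = 347.0
    sigma: float = 1.18
    low: int = 50

    def sample(self, rng: np.random.Generator, n: int, n_assays: int) -> np.ndarray:
        draws = rng.lognormal(mean=np.log(self.median), sigma=self.sigma, size=n)
        return np.clip(np.rint(draws).astype(int), self.low, n_assays)


@dataclass(frozen=True, slots=True)
class ActivitySimConfig:
    """Conditions of one simulated screening campaign."""

    n_assays: int = 600
    n_targets: int = 100
    frac_untargeted: float = 0.2
    assay_frequency_law: FrequencyLaw = field(default_factory=FrequencyLaw)
    background_hit_rate: float = 0.004
    promiscuous_hit_rate: float = 0.06
    overlap_level: float = 0.8
    confirmation_probability: float = 0.93
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.background_hit_rate < self.promiscuous_hit_rate <= 1):
            raise ValueError("need 0 <= background_hit_rate < promiscuous_hit_rate <= 1")
        if not (0 <= self.overlap_level <= 1):
            raise ValueError("overlap_level must lie in [0, 1]")
        if not (0 <= self.frac_untargeted <= 1):
            raise ValueError("frac_untargeted must lie in [0, 1]")
        if self.n_assays < 1:
            raise ValueError("n_assays must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: series memberships and the promiscuous id set."""

    planted_series: tuple[tuple[tuple[str, ...], str], ...]
    promiscuous_compounds: frozenset[str]

    def series_member_sets(self) -> list[frozenset[str]]:
        return [frozenset(members) for members, _ in self.planted_series]


# -- structure library --------------------------------------------------------

_DECOY_FRAMES = (
    "c1ccc2ccccc2c1",  # naphthalene
    "c1ccc2cc3ccccc3cc2c1",  # anthracene
    "c1ccc2ccc3ccccc3c2c1",  # phenanthrene
    "c1cc2ccc3cccc4ccc(c1)c2c34",  # pyrene
    "c1ccc2c(c1)ccc1ccc3ccccc3c12",  # chrysene
)


@lru_cache(maxsize=1)
def decoy_pool() -> tuple[str, ...]:
    """Enumerated pool of unique ring-only decoy structures.

    Aza-substitution patterns (up to three ring nitrogens at CH
    positions) over fused aromatic frames; every bond in every decoy is
    a ring bond, so no decoy admits a single-cut fragmentation.
    """
    seen: set[str] = set()
    for frame in _DECOY_FRAMES:
        base = Chem.MolFromSmiles(frame)
        n = base.GetNumAtoms()
        ch_positions = [a.GetIdx() for a in base.GetAtoms() if a.GetTotalNumHs() > 0]
        for k in range(0, 4):
            for pos in combinations(ch_positions, k):
                editable = Chem.RWMol(base)
                for p in pos:
                    atom = editable.GetAtomWithIdx(p)
                    atom.SetAtomicNum(7)
                    atom.SetNoImplicit(True)
                    atom.SetNumExplicitHs(0)
                try:
                    mol = editable.GetMol()
                    Chem.SanitizeMol(mol)
                except Exception:
                    continue
                seen.add(Chem.MolToSmiles(mol))
    return tuple(sorted(seen))


def _assemble(core_smiles: str, sub_smiles: str) -> str:
    core = Chem.MolFromSmiles(core_smiles)
    sub = Chem.MolFromSmiles(sub_smiles)
    mol = Chem.molzip(core, sub)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def generate_library(
    plans: Sequence[SeriesPlan],
    n_decoys: int,
    seed: int,
    promiscuous_decoy_fraction: float = 0.0,
) -> tuple[list[Molecule], GroundTruth]:
    """Build a library of planted series plus unrelated decoys.

    Every planted member is marked promiscuous in the returned
    :class:`GroundTruth` (series are planted among the high-hit-rate
    population, which is where series extraction operates);
    ``promiscuous_decoy_fraction`` of the decoys are additionally
    marked, so a population can carry a promiscuous tail of any size.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    rng = np.random.default_rng(seed)

    molecules: list[Molecule] = []
    planted: list[tuple[tuple[str, ...], str]] = []
    promiscuous: set[str] = set()

    for i, plan in enumerate(plans):
        if plan.core_template not in SCAFFOLDS:
            raise ConfigurationError(f"unknown scaffold identifier: {plan.core_template!r}")
        members: list[str] = []
        for j, sub_name in enumerate(plan.substituents):
            if sub_name not in SUBSTITUENTS:
                raise ConfigurationError(f"unknown substituent identifier: {sub_name!r}")
            smiles = _assemble(SCAFFOLDS[plan.core_template], SUBSTITUENTS[sub_name])
            mol_id = f"S{i:03d}M{j:02d}"
            molecules.append(canonicalize(smiles, mol_id))
            members.append(mol_id)
            promiscuous.add(mol_id)
        planted.append((tuple(members), plan.core_template))

    pool = list(decoy_pool())
    if n_decoys > len(pool):
        raise ConfigurationError(
            f"requested {n_decoys} decoys but the pool holds only {len(pool)}"
        )
    planted_canon = {m.canonical_smiles for m in molecules}
    order = rng.permutation(len(pool))
    taken = 0
    for idx in order:
        if taken >= n_decoys:
            break
        smiles = pool[idx]
        if smiles in planted_canon:
            continue
        mol_id = f"D{taken:04d}"
        molecules.append(canonicalize(smiles, mol_id))
        taken += 1
    decoy_ids = [m.id for m in molecules if m.id.startswith("D")]
    n_promiscuous_decoys = int(round(promiscuous_decoy_fraction * len(decoy_ids)))
    promiscuous.update(decoy_ids[:n_promiscuous_decoys])

    truth = GroundTruth(
        planted_series=tuple(planted),
        promiscuous_compounds=frozenset(promiscuous),
    )
    return molecules, truth


# -- activity matrix -----------------------------------------------------------


def generate_activity(
    molecules: Sequence[Molecule],
    truth: GroundTruth,
    cfg: ActivitySimConfig,
) -> list[ActivityRecord]:
    """Simulate primary (and paired confirmatory) screening records.

    Assay frequency follows ``cfg.assay_frequency_law``; series members
    share one frequency draw and a common base assay set of size
    ``overlap_level x frequency`` plus independent private sets (at
    overlap 1 their tested sets are identical). Activity is per-assay
    Bernoulli at the promiscuous rate for planted promiscuous compounds
    and at the background rate otherwise. Each compound with at least
    one primary active receives one confirmatory record: active with
    ``confirmation_probability``, else inactive.
    """
    if not molecules:
        raise ValueError("generate_activity requires at least one molecule")
    ids = [m.id for m in molecules]
    if len(set(ids)) != len(ids):
        raise ValueError("molecule ids must be unique")

    rng = np.random.default_rng(cfg.seed)
    law = cfg.assay_frequency_law

    assay_ids = [f"A{k:05d}" for k in range(cfg.n_assays)]
    n_untargeted = int(round(cfg.frac_untargeted * cfg.n_assays))
    assay_target = {
        assay_ids[k]: (None if k < n_untargeted else f"T{(k - n_untargeted) % cfg.n_targets:04d}")
        for k in range(cfg.n_assays)
    }

    # tested-assay set per compound (indices into assay_ids)
    tested_idx: dict[str, np.ndarray] = {}
    in_series = {m for members, _ in truth.planted_series for m in members}
    for members, _ in truth.planted_series:
        present = [m for m in members if m in set(ids)]
        if not present:
            continue
        freq = int(law.sample(rng, 1, cfg.n_assays)[0])
        n_base = int(round(cfg.overlap_level * freq))
        base = rng.choice(cfg.n_assays, size=n_base, replace=False)
        remaining = np.setdiff1d(np.arange(cfg.n_assays), base)
        for m in present:
            n_private = freq - n_base
            if n_private > 0 and len(remaining) > 0:
                private = rng.choice(remaining, size=min(n_private, len(remaining)), replace=False)
                tested_idx[m] = np.sort(np.concatenate([base, private]))
            else:
                tested_idx[m] = np.sort(base)

    singles = [i for i in ids if i not in in_series]
    freqs = law.sample(rng, len(singles), cfg.n_assays)
    for mol_id, freq in zip(singles, freqs):
        tested_idx[mol_id] = np.sort(rng.choice(cfg.n_assays, size=int(freq), replace=False))

    records: list[ActivityRecord] = []
    for mol_id in ids:
        tested = tested_idx[mol_id]
        rate = (
            cfg.promiscuous_hit_rate
            if mol_id in truth.promiscuous_compounds
            else cfg.background_hit_rate
        )
        active_mask = rng.random(len(tested)) < rate
        first_active: str | None = None
        for k, assay_idx in enumerate(tested):
            assay = assay_ids[assay_idx]
            outcome = "active" if active_mask[k] else "inactive"
            if outcome == "active" and first_active is None:
                first_active = assay
            records.append(
                ActivityRecord(
                    compound_id=mol_id,
                    assay_id=assay,
                    outcome=outcome,
                    stage="primary",
                    target_id=assay_target[assay],
                )
            )
        if first_active is not None:
            confirmed = rng.random() < cfg.confirmation_probability
            records.append(
                ActivityRecord(
                    compound_id=mol_id,
                    assay_id=f"C_{first_active}",
                    outcome="active" if confirmed else "inactive",
                    stage="confirmatory",
                    target_id=assay_target[first_active],
                )
            )
    return records


# -- ground-truth serialization -------------------------------------------------


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    payload = {
        "planted_series": [
            {"members": list(members), "core": core} for members, core in truth.planted_series
        ],
        "promiscuous_compounds": sorted(truth.promiscuous_compounds),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        planted_series=tuple(
            (tuple(e["members"]), e["core"]) for e in payload["planted_series"]
        ),
        promiscuous_compounds=frozenset(payload["promiscuous_compounds"]),
    )
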