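"""Shared fixtures: tiny activity matrices, libraries, and catalogs.

All fixtures are generated programmatically; nothing is read from
checked-in data files.
"""

from __future__ import annotations

import pytest

import hitseries as hs

# Self-authored compact catalog of representative PAINS-style motifs
# (a stand-in for a full filter catalog; family names follow the
# conventional vocabulary but patterns are written here for tests).
MINI_PAINS = [
    ("ene_rhodanine", "[#6]=C1SC(=S)NC1=O"),
    ("quinone_A", "O=C1C=CC(=O)C=C1"),
    ("catechol_A", "[OX2H]c1ccccc1[OX2H]"),
    ("azo_A", "cN=Nc"),
    ("hzone_phenol_A", "[OX2H]c1ccccc1/C=N/N"),
    ("anil_di_alk_A", "c1ccc(N(C)C)cc1N"),
    ("thiourea_A", "NC(=S)N"),
    ("nitroso_A", "[#6][NX2]=O"),
    ("ene_one_ene_A", "C=CC(=O)C=C"),
    ("mannich_A", "[OX2H]c1ccccc1CN(C)C"),
]


@pytest.fixture()
def mini_pains_file(tmp_path):
    path = tmp_path / "pains_mini.tsv"
    path.write_text("".join(f"{smarts}\t{family}\n" for family, smarts in MINI_PAINS))
    return path


@pytest.fixture()
def aggregator_file(tmp_path):
    # miconazole-like and a simple flavone, as stand-in aggregator entries
    path = tmp_path / "aggregators.smi"
    path.write_text(
        "O=c1cc(-c2ccccc2)oc2ccccc12 AGG1\n"
        "Cc1ccc(O)cc1 AGG2\n"
    )
    return path


def toy_records() -> list[hs.ActivityRecord]:
    """Two analogs: A tested in assays 1..10 (active in 1), B tested in
    6..15 (active in 6 and 7). Primary stage only."""
    records = []
    for k in range(1, 11):
        records.append(
            hs.ActivityRecord("A", f"a{k:02d}", "active" if k == 1 else "inactive", "primary")
        )
    for k in range(6, 16):
        records.append(
            hs.ActivityRecord("B", f"a{k:02d}", "active" if k in (6, 7) else "inactive", "primary")
        )
    return records


@pytest.fixture()
def toy_matrix() -> hs.ActivityMatrix:
    return hs.ingest_records(toy_records())


@pytest.fixture()
def toy_pair_mms() -> hs.MMS:
    return hs.MMS(
        core="*c1ccccc1", members=frozenset({"A", "B"}), substituents={"A": "*C", "B": "*CC"}
    )


def make_plans(n: int, sizes: list[int] | None = None) -> list[hs.SeriesPlan]:
    """Deterministic plans over the built-in vocabulary, one scaffold each.

    Uses only the fused-ring scaffolds, which are pairwise core-disjoint
    under single-cut fragmentation, so planted series are recoverable
    exactly.
    """
    scaffold_names = list(hs.RING_SCAFFOLDS)
    sub_names = sorted(hs.SUBSTITUENTS)
    if n > len(scaffold_names):
        raise ValueError("one distinct scaffold per plan required")
    plans = []
    for i in range(n):
        size = sizes[i % len(sizes)] if sizes else 2 + i % 5
        subs = tuple(sub_names[(i * 7 + j * 3) % len(sub_names)] for j in range(size))
        # regenerate on collision within the plan
        if len(set(subs)) != size:
            subs = tuple(sub_names[(i + j) % len(sub_names)] for j in range(size))
        plans.append(hs.SeriesPlan(core_template=scaffold_names[i], substituents=subs))
    return plans
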