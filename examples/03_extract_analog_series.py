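"""Matched molecular pairs and series from a small structure set.

Fragments each molecule at exocyclic single bonds, indexes the cuts by
core, and assembles analog series sharing one substitution site.
"""

import hitseries as hs

smiles = [
    ("Cc1ccc2ccccc2c1", "methyl_naphthalene"),
    ("CCc1ccc2ccccc2c1", "ethyl_naphthalene"),
    ("Clc1ccc2ccccc2c1", "chloro_naphthalene"),
    ("COc1ccc2ccccc2c1", "methoxy_naphthalene"),
    ("Cc1ccc2ncccc2c1", "methyl_quinoline"),
    ("CCc1ccc2ncccc2c1", "ethyl_quinoline"),
    ("c1ccc2ccccc2c1", "naphthalene_bare"),
]
molecules = [hs.canonicalize(s, i) for s, i in smiles]

mmps = hs.find_mmps(molecules, rules="exocyclic")
series = hs.remove_redundant(hs.build_mms(mmps))

print(f"{len(molecules)} molecules -> {len(mmps)} matched molecular pairs")
for s in series:
    print(f"core {s.core}: {s.size} members")
    for m in s.sorted_members():
        print(f"   {m:<22} substituent {s.substituents[m]}")
# Two series emerge - one per ring system - because a matched pair
# requires an identical core; the unsubstituted naphthalene has no
# exocyclic bond to cut and joins neither.
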