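"""PAINS and aggregator flagging with the reference filter catalog.

Checks a 5-arylidene rhodanine (a classical interference substructure)
and an innocuous analog against RDKit's 480-family PAINS collection and
a one-entry aggregator list.
"""

import hitseries as hs

catalog = hs.reference_pains_catalog()
print(f"reference PAINS catalog: {len(catalog)} families")

rhodanine = hs.canonicalize("O=C1NC(=S)SC1=Cc1ccccc1", "benzylidene_rhodanine")
plain = hs.canonicalize("CCOC(=O)c1ccc2ccccc2c1", "naphthoate_ester")
aggregators = frozenset({hs.canonicalize("O=c1cc(-c2ccccc2)oc2ccccc12", "flavone").canonical_smiles})

for mol in (rhodanine, plain):
    flags = hs.flag_compound(mol, catalog, aggregators)
    fams = ", ".join(flags.pains_families) or "none"
    print(f"{mol.id}: PAINS families [{fams}], aggregator={flags.is_aggregator}")

# census over two toy series, one containing the rhodanine
s1 = hs.MMS(core="*c1", members=frozenset({"benzylidene_rhodanine", "naphthoate_ester"}),
            substituents={"benzylidene_rhodanine": "*C", "naphthoate_ester": "*CC"})
flags = hs.flag_library([rhodanine, plain], catalog, aggregators)
c = hs.census([s1], flags)
print(f"census: aggregator={c.n_mms_with_aggregator}, pains={c.n_mms_with_pains}, "
      f"both={c.n_mms_with_both}, clean={c.n_mms_clean}")
# A series is flagged as soon as one member is: interference potential
# anywhere in an analog series taints its pooled hit-rate statistics.
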