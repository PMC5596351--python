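"""The three series parameters on a hand-checkable toy case.

Analog A was tested in assays 1..10 (active in 1), analog B in assays
6..15 (active in 6 and 7). Union 15 assays, 3 with activity; shared 5,
of which 2 with mixed outcomes.
"""

import hitseries as hs

records = []
for k in range(1, 11):
    records.append(hs.ActivityRecord(
        "A", f"a{k:02d}", "active" if k == 1 else "inactive", "primary"))
for k in range(6, 16):
    records.append(hs.ActivityRecord(
        "B", f"a{k:02d}", "active" if k in (6, 7) else "inactive", "primary"))
matrix = hs.ingest_records(records)

mms = hs.MMS(core="*c1ccc2ccccc2c1", members=frozenset({"A", "B"}),
             substituents={"A": "*C", "B": "*CC"})
p = hs.profile_mms(mms, matrix)

print(f"assay union {p.n_union_assays}, active assays {p.n_union_active}")
print(f"series hit rate   HR = {p.n_union_active}/{p.n_union_assays} = {p.hr:.3f}")
print(f"assay overlap        = {p.n_shared_assays}/{p.n_union_assays} = {p.overlap:.3f}")
print(f"inconsistent assays  = 2/{p.n_shared_assays} = {p.inconsistent:.3f}")
# HR pools activity over all assays any analog touched; overlap says how
# comparable the analogs' assay histories are; the inconsistent fraction
# counts shared assays where one analog was active and the other was not.
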