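"""Build a small on-farm lineage by hand and query it.

A wheat population is reproduced twice on its home farm, a bag of seed is
passed to a neighbour, and the neighbour grows it once.  The script prints
the pedigree and the generation numbers of the final harvest.
"""

import seedtrace as st

store = st.Store()
store.register(st.Location("Farm-A"))
store.register(st.Location("Farm-B"))
store.register(st.Person("Alice", role="farmer", location="Farm-A"))
store.register(st.Person("Bob", role="farmer", location="Farm-B"))
store.register(st.Germplasm("Rouge-de-Bordeaux", "Triticum aestivum"))

origin = store.create_seed_lot("Rouge-de-Bordeaux", "Farm-A", 2015, 1000)
print(f"origin lot: {origin.name} ({origin.initial_quantity_g} g)")

lot = origin
for sow_year in (2015, 2016):
    result = st.record_event(store, st.EventSpec(
        kind="reproduction",
        date=st.FlexDate(sow_year, 10, 20),
        location="Farm-A",
        parents=[(lot.name, 150)],
        actor="Alice",
        harvest_date=st.FlexDate(sow_year + 1, 7, 15),
        harvested_quantity_g=2200,
    ))
    lot = result.children[0]
    print(f"reproduced -> {lot.name}")

moved = st.record_diffusion(store, lot.name, "Farm-B", "Bob", 200, st.FlexDate(2017, 8, 20))
print(f"diffused 200 g -> {moved.children[0].name}")

final = st.record_event(store, st.EventSpec(
    kind="reproduction",
    date=st.FlexDate(2017, 10, 20),
    location="Farm-B",
    parents=[(moved.children[0].name, 150)],
    actor="Bob",
    harvest_date=st.FlexDate(2018, 7, 10),
    harvested_quantity_g=1900,
)).children[0]

print(f"\nancestors of {final.name}:")
for name in sorted(st.ancestors(store, final.name)):
    print(f"  {name}")

info = st.generation(store, final.name)
# total: reproduction events since the origin; local: the trailing run at
# Farm-B only (the diffusion broke the local count); exact: full history known
print(f"\ngeneration: total={info.total} local={info.local} quality={info.quality}")
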