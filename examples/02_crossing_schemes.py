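"""Multi-step crossing schemes: backcross and polycross.

Any crossing scheme is described step by step with two-parent cross
events: a backcross is AxB -> C then CxB, a polycross is AxB -> C and
DxE -> F followed by FxC.  An open-pollinated blend of several parents is
recorded as a mixture.  The script prints each child's auto-derived
germplasm name and the final ancestor sets.
"""

import seedtrace as st

store = st.Store()
store.register(st.Location("Station", kind="station"))
for name in "ABDE":
    store.register(st.Germplasm(name, "Triticum aestivum"))
    store.create_seed_lot(name, "Station", 2015, 500, name=f"{name}-lot")


def cross(mother, father, year):
    result = st.record_event(store, st.EventSpec(
        "cross", st.FlexDate(year, 6, 1), "Station",
        parents=[(mother, None), (father, None)], mother=mother, father=father,
    ))
    child = result.children[0]
    print(f"{mother} x {father} -> {child.name}  (germplasm {child.germplasm_key[0]!r})")
    return child


c = cross("A-lot", "B-lot", 2016)
backcross = cross(c.name, "B-lot", 2017)

f = cross("D-lot", "E-lot", 2016)
polycross = cross(f.name, c.name, 2018)

mix = st.record_event(store, st.EventSpec(
    "mixture", st.FlexDate(2019, 9, 1), "Station",
    parents=[("A-lot", 100), ("B-lot", 100), ("D-lot", 100), ("E-lot", 100)],
))
print(f"mixture of 4 lots -> {mix.children[0].name} (germplasm {mix.children[0].germplasm_key[0]!r})")

# the pedigree query confirms each composition reaches the intended founders
print(f"\nbackcross ancestors: {sorted(st.ancestors(store, backcross.name))}")
print(f"polycross ancestors: {sorted(st.ancestors(store, polycross.name))}")
gen = st.generation(store, polycross.name)
print(f"polycross generation: total={gen.total} (a cross resets the count)")
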