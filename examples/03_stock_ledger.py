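"""Gram-based stock accounting with inventory resets.

A lot starts at 1000 g, loses 300 g to a sowing, is re-measured at 600 g
during a winter inventory (the absolute measurement overrides the computed
balance), then loses another 100 g.  The script prints the replayed ledger
and the current balance.
"""

import seedtrace as st

store = st.Store()
store.register(st.Location("Farm-A"))
store.register(st.Location("Farm-B"))
store.register(st.Person("Bob", location="Farm-B"))
store.register(st.Germplasm("Renan", "Triticum aestivum"))
lot = store.create_seed_lot("Renan", "Farm-A", 2015, 1000)

st.record_event(store, st.EventSpec(
    "reproduction", st.FlexDate(2016, 8, 1), "Farm-A", parents=[(lot.name, 300)],
))
store.add_inventory(lot.name, st.FlexDate(2016, 12, 1), 600)
st.record_diffusion(store, lot.name, "Farm-B", "Bob", 100, st.FlexDate(2017, 3, 1))

print(st.history_tsv(store, lot.name))
current, warnings = st.current_stock(store, lot.name)
print(f"current stock: {current:g} g")  # 500 = 600 (inventory) - 100

mid_season, _ = st.current_stock(store, lot.name, as_of=st.FlexDate(2016, 12, 15))
print(f"as of 2016-12-15: {mid_season:g} g")  # the inventory had just reset it to 600

# unknown quantities are never silently treated as zero
vague = store.create_seed_lot("Renan", "Farm-A", 2016, None)
st.record_diffusion(store, vague.name, "Farm-B", "Bob", 200, st.FlexDate(2017, 8, 1))
balance, warns = st.current_stock(store, vague.name)
print(f"\nlot with unknown initial stock after a 200 g debit: {balance:g} g")
for w in warns:
    print(f"  warning: {w}")
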