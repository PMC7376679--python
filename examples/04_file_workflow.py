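"""The tabulated-file workflow: template -> fill -> import -> report.

Field data travels as TSV files: export a pre-filled reproduction template
for the lots to be sown, fill the remaining cells (here, in code; in
practice, a spreadsheet), and submit it.  The import validates the whole
file first and applies it atomically; the report lists every issue with
its row number.  A second, corrupted submission shows the rejection path.
"""

import seedtrace as st

store = st.Store()
store.register(st.Location("Farm-A"))
store.register(st.Person("Alice", location="Farm-A"))
store.register(st.Germplasm("Touselle", "Triticum aestivum"))
for year in (2015, 2016):
    store.create_seed_lot("Touselle", "Farm-A", year, 800)

template = st.export_template(store, sorted(store.lots), "reproduction")
print("exported template:")
print(template)

header, *rows = template.strip().split("\n")
columns = header.split("\t")
filled_rows = []
for row in rows:
    cells = dict(zip(columns, row.split("\t")))
    cells.update({
        "sowing_date": "2017-10-20", "actor": "Alice", "quantity_sown_g": "150",
        "harvest_date": "2018-07-15", "quantity_harvested_g": "1850",
    })
    filled_rows.append("\t".join(cells[c] for c in columns))
# an extra column records a measured variable; '#harvest' attaches it to the
# harvested lot instead of the sowing->harvest relation
filled = "\n".join([header + "\ttkw:balance#harvest"] + [r + "\t46.5" for r in filled_rows])

report = st.import_file(store, "reproduction", filled)
print(report.render_text())
print(f"-> {report.events_created} events, {report.lots_created} new lots, "
      f"{report.data_points_created} data points\n")

bad = filled.replace("Touselle_Farm-A_2016", "Touselle_Farm-A_1999")
before = store.dumps()
rejected = st.import_file(store, "reproduction", bad)
print(rejected.render_text())
print(f"store untouched by the rejected file: {store.dumps() == before}")

# a reproduction file also drives deletion of the events it lists (cascade
# removes all downstream events, lots and data as well)
export = st.export_events(store, "reproduction")
deletion = st.delete_from_file(store, export, cascade=True)
print(f"\ndeleted {len(deletion.events_deleted)} events and {len(deletion.lots_deleted)} lots by file")
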