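# seedtrace

A traceability engine for seed-lot networks, written for participatory
plant breeding (PPB) programs and on-farm experimentation where seed moves
between many farms and changes with every season.

The atomic unit is the **seed lot**: a named quantity of seeds of one
germplasm (a variety, population or line of any cultivated species), held
at one location, produced or acquired in one year. Lots are linked by
directed parent → child **relations**, each owned by one of five typed
**events**:

| kind | parents | meaning |
|---|---|---|
| reproduction | 1 | sow a lot, harvest a new lot of the same germplasm |
| cross | 2 | mate a mother and a father lot, creating a new germplasm |
| selection | 1 | extract one or more derivative lots (e.g. selected spikes) |
| mixture | ≥ 2 | blend several lots into one new genetic entity |
| diffusion | 1 | pass seed to another actor/location |

The relation graph is a DAG at all times. Multi-step composition
expresses any crossing scheme: a backcross is `A×B → C` then `C×B`; a
polycross is `A×B → C`, `D×E → F`, then `F×C`; open pollination among
several parents is a mixture. On top of the graph the library provides:

- **generation counting** — `generation(lot)` returns the maximal number
  of reproduction events along any ancestry path (crosses and mixtures
  reset the count), the *local* trailing run at the lot's own location
  (a diffusion breaks it), and an `exact`/`minimum` quality flag that
  turns to `minimum` when some ancestry path ends in a lot with no
  recorded parents that is not marked as an origin;
- a **gram-based stock ledger** — balance replayed from the initial
  quantity, every relation debit, and dated absolute inventory
  measurements that reset the balance; unknown quantities stay unknown
  (never 0) and negative balances are flagged, never clamped;
- **six tabulated (TSV) file formats** — one per event kind plus an
  individual-measures format — with mandatory headers, free extra
  *variable columns* for measured data (`name[:method][@date][#harvest]`),
  two-phase atomic imports with row-by-row reports, pre-filled template
  export, and file-driven deletion (alone or in cascade);
- a **query API** — three-table data queries under conjunctive filters,
  seed-lot cards (identity / history / data / stock) and relation cards
  (info / data), and ranked auto-complete search;
- a deterministic **synthetic network generator** for testing and demos;
- a thin **command-line shell** (`seedtrace`) over a single-file store.

## A worked example

```python
import seedtrace as st

store = st.Store()
store.register(st.Location("Farm-A")); store.register(st.Location("Farm-B"))
store.register(st.Person("Bob", location="Farm-B"))
store.register(st.Germplasm("Rouge-de-Bordeaux", "Triticum aestivum"))
origin = store.create_seed_lot("Rouge-de-Bordeaux", "Farm-A", 2015, 1000)

r1 = st.record_event(store, st.EventSpec(
    "reproduction", st.FlexDate(2015, 10, 20), "Farm-A",
    parents=[(origin.name, 150)],
    harvest_date=st.FlexDate(2016, 7, 15), harvested_quantity_g=2200))
d = st.record_diffusion(store, r1.children[0].name, "Farm-B", "Bob",
                        200, st.FlexDate(2016, 8, 20))

print(st.generation(store, d.children[0].name))
print(st.current_stock(store, origin.name))
print(st.current_stock(store, r1.children[0].name))
```

prints

```
GenerationInfo(total=1, local=0, quality='exact')
(850.0, [])
(2000.0, [])
```

— the diffusion child is one reproduction away from the origin in total
but has no local run yet at Farm-B; the origin lost its 150 g sowing
(1000 − 150) and the harvested lot its 200 g gift (2200 − 200). The
`examples/` directory holds five short narrative scripts, one per
capability (lineage basics, crossing schemes, the stock ledger, the
file workflow, the synthetic generator), each printing the numbers it
computes and what they mean.

## Command line

```sh
seedtrace --store net.db init
seedtrace --store net.db import reproduction sowing_2016.tsv
seedtrace --store net.db template reproduction --select Renan --out next.tsv
seedtrace --store net.db stock Renan_Farm-A_2015
seedtrace --store net.db card Renan_Farm-A_2015
seedtrace --store net.db delete --file recorded.tsv --cascade
```

Exit codes: 0 success, 1 rejected import or validation failure, 2 usage
error. A rejected import leaves the store byte-identical.

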