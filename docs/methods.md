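# Methods

## The data model

A seed-lot network is a directed acyclic graph. Nodes are **seed lots**
(name, germplasm, stock location, creation year, optional initial grams);
edges are **relations** (parent lot → child lot, grams taken from the
parent, owning event). Every relation belongs to exactly one **event** of
five kinds — reproduction, cross, selection, mixture, diffusion — with a
date, a location, an optional actor and project. Measured values
(**raw data**) attach to exactly one lot or one relation and are described
by a **variable** (with a phenotype/environment/practice scope and a
global/individual level) and optionally a **method**. **Inventory
updates** are dated absolute stock measurements. Entities are identified
by natural keys: lots by name, germplasms by the (name, species) pair,
everything else by name — names are what users write in files. Species
are free text; the model is deliberately agnostic of taxonomy so any
cultivated species (or several at once) can be managed.

The acyclicity invariant is enforced on every relation insertion (a
reachability check from the would-be child) and re-verified by a
networkx topological check in `validate_integrity()`, which also asserts
that every reference resolves. The store is in-memory with single-file
sqlite persistence; `dumps()` produces a canonical JSON serialization in
which equal content is byte-identical, the oracle used for atomicity
checks throughout.

## Event semantics

Parent multiplicity is fixed per kind (reproduction/selection/diffusion 1,
cross 2, mixture ≥ 2). Each event creates exactly one child lot, except a
selection with k labels, which creates k children and k relations (every
auto-created lot must own a parent relation, so the one-relation-per-parent
rule cannot hold there). Child lots inherit the parent germplasm for
reproduction, selection and diffusion. A cross registers a new germplasm
named `<mother> x <father>` (mother first, as crossing schemes are
conventionally written); a mixture derives `<name> + <name> + ...` from the
sorted distinct parent germplasm names unless an explicit name is given —
a blend is a new genetic entity. Child-lot names follow
`<germplasm>_<location>_<year>`; underscores inside components are mapped
to hyphens so the pattern stays parseable, and collisions get an `_<n>`
suffix (n ≥ 2). The pattern is deterministic, which is what makes
export → re-import round trips exact.

Three quantity conventions, chosen where the design was open:

- a reproduction child's initial quantity is the harvested quantity when
  recorded; harvests never credit the parent lot (the sowing debit is the
  only parent-side effect);
- a diffusion child's initial quantity is the grams moved; a mixture
  child's is the sum of parent contributions when all are known;
- unknown quantities are permitted everywhere, recorded as unknown,
  leave the ledger untouched and emit a warning — files coming back from
  farms are routinely incomplete, and silently coercing to zero would
  corrupt stock figures.

A reproduction child's creation year is taken from the harvest date when
present (cereals are sown in autumn and harvested the following summer),
falling back to the event year; other kinds use the event year.

## Generation counting

"Generation number" is not a single well-defined notion in a network with
crosses, blends and transfers; the rule implemented here is isolated
behind `GenerationInfo` so an alternate rule is swappable:

- **total** — the maximum over ancestry paths of the number of
  reproduction events since the nearest cross or mixture event (which
  reset the count: they create a new genetic entity) or since an origin
  lot. Selection and diffusion are transparent: they neither count nor
  reset. Whether selection should count is debatable; we do not count it
  and flag this choice for users.
- **local** — the length of the maximal trailing run of reproduction
  events whose event location equals the lot's own location; any other
  event (a diffusion in particular, or a reproduction elsewhere) breaks
  the run. By construction local ≤ total.
- **quality** — `exact` when every ancestry path ends at a lot flagged as
  an origin; `minimum` when some path ends at a parentless lot without
  the origin flag, i.e. the recorded history is truncated and the true
  counts can only be larger. Missing history is the only uncertainty the
  schema can represent, so the flag is driven by it alone.

Both counts are computed by memoized traversal over the DAG; the test
suite checks them against an independent exhaustive path-enumeration
oracle on generated networks of up to 50 lots.

## Stock ledger

A lot's balance is replayed from an ordered ledger: the *initial* credit
(absent when unknown), one *debit* per relation in which the lot is a
parent with a known quantity, and *inventory* resets that override the
running balance with the measured value. Ordering depends only on
(date, kind, source id) — never on insertion order — with the tie rule
initial < debit < inventory at equal dates: an inventory taken the day of
a sowing reflects post-sowing reality. Year-only dates sort as July 1 of
their year (mid-season for a northern-hemisphere cereal calendar); the
original precision is kept for display. Quantities are decimal grams at
0.1 g resolution. When the initial quantity is unknown the replay starts
from 0 with an explicit warning, so debits drive the balance negative
rather than pretending a zero stock was real; negative balances are
always preserved and flagged because they reveal data-entry errors.
`current_stock(as_of=...)` returns `None` (unknown) when no entry exists
at or before the cut-off — deliberately distinct from 0 g.

## Tabulated files

Six TSV formats: one per event kind plus an individual-measures format.
UTF-8, tab-separated, empty cell = missing. The mandatory header names
are this package's documented dialect (registered in one place,
`formats.FORMATS`); sites with their own column names remap them
bijectively through configuration. Beyond the mandatory headers, any
extra column is a *variable column* `name[:method][@date][#harvest]`:
non-empty cells become raw data attached to the row's relation, or to the
harvested/child lot when the `#harvest` suffix is present; a column-level
date overrides the row's event date. Unregistered variables are
auto-registered with a warning (global level in event files, individual
level in the measures file). Dates accept ISO `YYYY-MM-DD`, day-first
`DD/MM/YYYY` (never month-first, by contract) and bare `YYYY`.

Imports are two-phase: the whole file is validated and applied against a
deep-copied snapshot while collecting every issue; the snapshot replaces
the store only when zero errors were found. Unknown parent lots, missing
mandatory headers, bad numbers/dates, multiplicity violations and
duplicate event ids within a file are errors; unknown quantities and
auto-registrations are warnings. Rows sharing an event id form one event
in the mixture format (one parent per row) and the selection format (one
label per row). Re-submitting an already-recorded event id skips the row
with a warning, and a template row whose fillable cells are all empty is
skipped as a no-op — together these make re-importing an untouched or
already-imported export harmless. Template export pre-fills the
identifier, parent-lot and location columns and assigns deterministic
event ids (`<kind>:<lot>`). `export_events` re-emits recorded events as
import-compatible files; the same reproduction format drives deletion
(alone, or in cascade over all downstream events, lots and attached
data), with the whole file rejected if any row fails to resolve.

## Synthetic networks

The generator emulates the structure of a PPB seed-exchange network, not
its agronomy: every held lot is reproduced each season; harvests are then
(with configured per-lot or per-farm probabilities) selected from,
crossed, diffused to a random other farm, or blended. Defaults model a
small wheat network: 5 farms, 3 populations, 4 seasons, ~1 kg origin
lots, 150 g sown per plot, harvest-to-sown ratio uniform in 8–25
(ordinary magnitudes for on-farm small-grain plots), 200 g diffusions,
100 g mixture draws, 50 g spike selections, and diffusion/selection/
cross/mixture probabilities 0.15/0.10/0.05/0.05 per opportunity. All
randomness flows from one seeded `random.Random`; identical scenarios are
byte-identical, including the emitted files. Within a year the stochastic
phases run in a fixed kind order (selection, cross, diffusion, mixture)
matching the order of the emitted per-year files, so re-importing the
files replays the exact creation order — this is what makes the
round-trip byte-identical rather than merely isomorphic. The manifest
records ground-truth counts (lots, events per kind, data points, total
grams debited) plus everything files cannot express (origin lots,
locations, actors), from which `prepare_import_store` rebuilds the
starting state. What passing tests on these networks do **not** show:
robustness to free-form real-world files (hand-edited spreadsheets with
stray encodings or merged cells), to genuinely conflicting histories
entered by different actors, or to scales beyond a few thousand lots.

## Test and acceptance problem sizes

Property suites run on small scenarios (2 farms × 2 germplasms × 2–3
seasons, a few dozen lots each) so that hundreds of independently seeded
networks — 200 for the ledger closed-form check, 20 for the generation
oracle, 10 each for deletion integrity and import atomicity — execute in
seconds; the properties themselves are size-agnostic. The acceptance
script uses the same sizes and derives every per-network seed from its
`--seed` argument.

## Known limitations

- One store, one writer: no concurrency control beyond whole-file saves.
- The generation rule and the header names are package conventions, not
  community standards; both are isolated (in `GenerationInfo` and
  `formats.FORMATS`) for that reason.
- Inventory updates model absolute re-measurements only; additions
  (purchases, returns) must be entered as new lots.
- Relation lookup on cards is by (parent, child) pair; repeated events on
  the same pair are listed newest first rather than disambiguated.
- No kinship or genetic-relatedness computation — ancestry is purely the
  recorded relation graph.
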