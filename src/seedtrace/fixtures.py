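"""Deterministic synthetic seed-exchange networks.

Emulates a decentralised participatory-breeding network: a set of farms
each starting with origin lots of a few germplasms, reproducing every held
lot each season, and occasionally diffusing seed to another farm, blending
lots, selecting derivatives, or crossing two germplasms.  The generator
returns the populated store, the corresponding tabulated files (in an
import order that respects lineage), and a ground-truth manifest of exact
expected counts for oracle tests.  Identical scenarios (same seed) produce
byte-identical output; only network and ledger structure is simulated — no
agronomy, genetics or trait realism.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .dates import FlexDate
from .errors import ValidationError
from .events import EventSpec, record_event
from .io import export_events, _write_tsv
from .model import EVENT_KINDS, Germplasm, Location, Person, Store, Variable, round_grams

_KIND_ORDER = {"reproduction": 0, "selection": 1, "cross": 2, "diffusion": 3, "mixture": 4}


@dataclass(frozen=True)
class NetworkScenario:
    """Study conditions for one synthetic network.

    Probabilities are per lot-year (diffusion, selection, cross) or per
    farm-year (mixture).  Quantities follow a small-grain cereal scale:
    ~1 kg origin lots, 150 g sown per plot, and a harvest-to-sown weight
    ratio drawn between 8 and 25.
    """

    n_farms: int = 5
    n_germplasms: int = 3
    n_years: int = 4
    p_diffusion: float = 0.15
    p_mixture: float = 0.05
    p_selection: float = 0.1
    p_cross: float = 0.05
    rng_seed: int = 0
    start_year: int = 2015
    initial_g: float = 1000.0
    sown_g: float = 150.0
    harvest_mult: tuple[float, float] = (8.0, 25.0)
    diffusion_g: float = 200.0
    mixture_g: float = 100.0
    selection_g: float = 50.0
    species: str = "Triticum aestivum"
    n_measured_individuals: int = 0  # per harvested lot and year, plant_height measures

    def validate(self) -> None:
        for name in ("p_diffusion", "p_mixture", "p_selection", "p_cross"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.n_farms < 1 or self.n_germplasms < 1 or self.n_years < 0:
            raise ValidationError("n_farms and n_germplasms must be >= 1 and n_years >= 0")
        if self.harvest_mult[0] > self.harvest_mult[1] or self.harvest_mult[0] <= 0:
            raise ValidationError("harvest_mult must be a positive (low, high) range")
        if min(self.initial_g, self.sown_g, self.diffusion_g, self.mixture_g, self.selection_g) < 0:
            raise ValidationError("quantities must be >= 0")


@dataclass
class GeneratedNetwork:
    scenario: NetworkScenario
    store: Store
    files: list[tuple[str, str, str]]  # (filename, kind, text) in import order
    manifest: dict

    def write_files(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for filename, _, text in self.files:
            path = directory / filename
            path.write_text(text, encoding="utf-8")
            paths.append(path)
        return paths


def prepare_import_store(manifest: dict) -> Store:
    """Fresh store holding only what the files cannot express: locations,
    actors, origin germplasms and origin lots."""
    store = Store()
    for name in manifest["locations"]:
        store.register(Location(name, kind="farm"))
    for name in manifest["persons"]:
        store.register(Person(name, role="farmer", location=manifest["persons"][name]))
    for gname, species in manifest["origin_germplasms"]:
        store.register(Germplasm(gname, species))
    for lot in manifest["origin_lots"]:
        store.create_seed_lot(
            lot["germplasm"],
            lot["location"],
            lot["year"],
            initial_quantity_g=lot["initial_g"],
            name=lot["name"],
            species=lot["species"],
        )
    return store


def generate(scenario: NetworkScenario) -> GeneratedNetwork:
    """Build one network; see the module docstring for the life cycle."""
    scenario.validate()
    rng = random.Random(scenario.rng_seed)
    store = Store()

    farms = [f"Farm-{i + 1}" for i in range(scenario.n_farms)]
    for farm in farms:
        store.register(Location(farm, kind="farm"))
    farmers = {farm: f"Farmer-{i + 1}" for i, farm in enumerate(farms)}
    for farm, person in farmers.items():
        store.register(Person(person, role="farmer", location=farm))
    germplasms = [f"Pop{i + 1:02d}" for i in range(scenario.n_germplasms)]
    for g in germplasms:
        store.register(Germplasm(g, scenario.species))
    if scenario.n_measured_individuals:
        store.register(Variable("plant_height", scope="phenotype", level="individual"))

    origin_lots = []
    active: dict[str, list[str]] = {farm: [] for farm in farms}
    for farm in farms:
        for g in germplasms:
            lot = store.create_seed_lot(g, farm, scenario.start_year, scenario.initial_g, species=scenario.species)
            active[farm].append(lot.name)
            origin_lots.append(
                {
                    "name": lot.name,
                    "germplasm": g,
                    "species": scenario.species,
                    "location": farm,
                    "year": scenario.start_year,
                    "initial_g": scenario.initial_g,
                }
            )

    event_counts = {kind: 0 for kind in EVENT_KINDS}
    total_debit = 0.0
    files: list[tuple[str, str, str]] = []
    events_by_year_kind: dict[tuple[int, str], list[str]] = {}
    measure_rows: list[list[str]] = []

    def note(year_idx: int, kind: str, event_id: str, debits: float) -> None:
        nonlocal total_debit
        event_counts[kind] += 1
        total_debit = round(total_debit + debits, 1)
        events_by_year_kind.setdefault((year_idx, kind), []).append(event_id)

    for year_idx in range(1, scenario.n_years + 1):
        year = scenario.start_year + year_idx
        new_active: dict[str, list[str]] = {farm: [] for farm in farms}

        # every held lot is reproduced (sown previous autumn, harvested this summer)
        for farm in farms:
            for lot_name in active[farm]:
                mult = rng.uniform(*scenario.harvest_mult)
                harvested = round_grams(scenario.sown_g * mult)
                spec = EventSpec(
                    kind="reproduction",
                    date=FlexDate(year - 1, 10, 1 + rng.randrange(28)),
                    location=farm,
                    parents=[(lot_name, scenario.sown_g)],
                    actor=farmers[farm],
                    harvest_date=FlexDate(year, 7, 1 + rng.randrange(28)),
                    harvested_quantity_g=harvested,
                )
                result = record_event(store, spec)
                new_active[farm].append(result.children[0].name)
                note(year_idx, "reproduction", result.event.event_id, scenario.sown_g)
                if scenario.n_measured_individuals:
                    for i in range(1, scenario.n_measured_individuals + 1):
                        value = f"{rng.uniform(60, 140):.1f}"
                        date = FlexDate(year, 6, 15)
                        store.add_raw_data(
                            "lot", result.children[0].name, "plant_height", value, None, date, individual_index=i
                        )
                        measure_rows.append([result.children[0].name, str(i), date.isoformat(), value])

        # stochastic events on this year's harvests; phases run in the same
        # kind order as the emitted files so a re-import replays creation order
        for farm in farms:
            for lot_name in list(new_active[farm]):
                if rng.random() < scenario.p_selection:
                    spec = EventSpec(
                        kind="selection",
                        date=FlexDate(year, 7, 28),
                        location=farm,
                        parents=[(lot_name, None)],
                        selection_labels=[("spikes-1", scenario.selection_g)],
                        actor=farmers[farm],
                    )
                    result = record_event(store, spec)
                    new_active[farm].append(result.children[0].name)
                    note(year_idx, "selection", result.event.event_id, scenario.selection_g)
        # cross two distinct germplasms held on one farm
        for farm in farms:
            if rng.random() < scenario.p_cross:
                by_germplasm: dict[str, str] = {}
                for lot_name in new_active[farm]:
                    by_germplasm.setdefault(store.lots[lot_name].germplasm_key[0], lot_name)
                if len(by_germplasm) >= 2:
                    mother, father = rng.sample(sorted(by_germplasm.values()), 2)
                    spec = EventSpec(
                        kind="cross",
                        date=FlexDate(year, 6, 10),
                        location=farm,
                        parents=[(mother, None), (father, None)],
                        mother=mother,
                        father=father,
                        actor=farmers[farm],
                    )
                    result = record_event(store, spec)
                    new_active[farm].append(result.children[0].name)
                    note(year_idx, "cross", result.event.event_id, 0.0)
        # diffusion of part of a harvest to another farm
        if len(farms) > 1:
            for farm in farms:
                for lot_name in list(new_active[farm]):
                    if rng.random() < scenario.p_diffusion:
                        recipient = rng.choice([f for f in farms if f != farm])
                        # diffusion files carry no actor column, so none is recorded
                        spec = EventSpec(
                            kind="diffusion",
                            date=FlexDate(year, 8, 20),
                            location=farm,
                            parents=[(lot_name, scenario.diffusion_g)],
                            recipient_location=recipient,
                            recipient_person=farmers[recipient],
                        )
                        result = record_event(store, spec)
                        new_active[recipient].append(result.children[0].name)
                        note(year_idx, "diffusion", result.event.event_id, scenario.diffusion_g)
        # blend 2-4 lots held on one farm
        for farm in farms:
            if rng.random() < scenario.p_mixture and len(new_active[farm]) >= 2:
                k = min(len(new_active[farm]), rng.randint(2, 4))
                parents = rng.sample(sorted(new_active[farm]), k)
                spec = EventSpec(
                    kind="mixture",
                    date=FlexDate(year, 9, 5),
                    location=farm,
                    parents=[(p, scenario.mixture_g) for p in parents],
                    actor=farmers[farm],
                )
                result = record_event(store, spec)
                new_active[farm].append(result.children[0].name)
                note(year_idx, "mixture", result.event.event_id, scenario.mixture_g * k)

        active = new_active

    # emit files in an import order that respects lineage
    for (year_idx, kind) in sorted(events_by_year_kind, key=lambda yk: (yk[0], _KIND_ORDER[yk[1]])):
        ids = events_by_year_kind[(year_idx, kind)]
        filename = f"{year_idx:02d}_{kind}.tsv"
        files.append((filename, kind, export_events(store, kind, ids)))
    if measure_rows:
        header = ["subject_seed_lot", "individual_index", "date", "plant_height"]
        files.append((f"{scenario.n_years:02d}_individual_measures.tsv", "individual_measures", _write_tsv(header, measure_rows)))

    manifest = {
        "scenario_seed": scenario.rng_seed,
        "locations": farms,
        "persons": {person: farm for farm, person in farmers.items()},
        "origin_germplasms": [(g, scenario.species) for g in germplasms],
        "origin_lots": origin_lots,
        "n_lots": len(store.lots),
        "n_origin_lots": len(origin_lots),
        "events": dict(event_counts),
        "n_events": len(store.events),
        "n_relations": len(store.relations),
        "n_data_points": len(store.raw_data),
        "total_debit_g": round(total_debit, 1),
    }
    store.validate_integrity()
    return GeneratedNetwork(scenario=scenario, store=store, files=files, manifest=manifest)


# -- scenario config files ---------------------------------------------------

_FIELD_TYPES = {
    "n_farms": int,
    "n_germplasms": int,
    "n_years": int,
    "p_diffusion": float,
    "p_mixture": float,
    "p_selection": float,
    "p_cross": float,
    "rng_seed": int,
    "start_year": int,
    "initial_g": float,
    "sown_g": float,
    "diffusion_g": float,
    "mixture_g": float,
    "selection_g": float,
    "species": str,
    "n_measured_individuals": int,
}


def scenario_from_text(text: str) -> NetworkScenario:
    """Parse a plain ``key = value`` scenario config.

    ``harvest_mult`` takes two comma-separated numbers; ``#`` starts a
    comment.
    """
    kwargs = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"scenario line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "harvest_mult":
            parts = [p.strip() for p in value.split(",")]
            if len(parts) != 2:
                raise ValidationError("harvest_mult takes two comma-separated numbers")
            kwargs[key] = (float(parts[0]), float(parts[1]))
        elif key in _FIELD_TYPES:
            try:
                kwargs[key] = _FIELD_TYPES[key](value)
            except ValueError as exc:
                raise ValidationError(f"scenario line {lineno}: bad value for {key!r}") from exc
        else:
            raise ValidationError(f"scenario line {lineno}: unknown key {key!r}")
    scenario = NetworkScenario(**kwargs)
    scenario.validate()
    return scenario


def scenario_from_file(path: str | Path) -> NetworkScenario:
    return scenario_from_text(Path(path).read_text(encoding="utf-8"))
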