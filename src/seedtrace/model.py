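"""Domain types and the registry every other module operates on.

The traceable unit is the **seed lot**: a named quantity of seeds of one
germplasm, held at one location, produced or acquired in one year.  Lots
are linked by directed parent→child **relations**, each owned by one typed
**event** (reproduction, cross, selection, mixture or diffusion), and the
relation graph is kept acyclic at all times.  Measured values (phenotypes,
environment, cultural practices) attach to a lot or to a relation as
**raw data**, described by a variable and a method.

Natural keys are names: a seed lot by its name, a germplasm by the
``(name, species)`` pair, everything else by name — names are the
identifiers users write in files.  Quantities are decimal grams at 0.1 g
resolution; an unknown quantity is ``None``, never 0 (a lot with unknown
initial stock must not report a stock of 0 g).
"""

from __future__ import annotations

import copy
import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import networkx as nx

from .dates import FlexDate
from .errors import (
    CycleError,
    DuplicateKeyError,
    DuplicateNameError,
    UnknownEventError,
    UnknownLotError,
    ValidationError,
)

EVENT_KINDS: tuple[str, ...] = ("reproduction", "cross", "selection", "mixture", "diffusion")
LOCATION_KINDS: tuple[str, ...] = ("farm", "institute", "station", "other")
PERSON_ROLES: tuple[str, ...] = ("farmer", "facilitator", "researcher", "other")
VARIABLE_SCOPES: tuple[str, ...] = ("phenotype", "environment", "practice")
VARIABLE_LEVELS: tuple[str, ...] = ("global", "individual")


def round_grams(value: float | None) -> float | None:
    """Quantities are decimal grams kept at 0.1 g resolution."""
    if value is None:
        return None
    return round(float(value), 1)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GermplasmType:
    """Kind of genetic material: population, inbred line, hybrid, ..."""

    label: str

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("germplasm type label must be non-empty")


@dataclass(frozen=True)
class Germplasm:
    """Named genetic material; the species is part of the identity."""

    name: str
    species: str
    type_label: str = "population"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("germplasm name must be non-empty")
        if not self.species:
            raise ValidationError("germplasm species must be non-empty")

    @property
    def key(self) -> tuple[str, str]:
        return (self.name, self.species)


@dataclass(frozen=True)
class Location:
    """An experimentation site, institute or any legal entity holding seed."""

    name: str
    kind: str = "farm"
    region: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("location name must be non-empty")
        if self.kind not in LOCATION_KINDS:
            raise ValidationError(f"location kind must be one of {LOCATION_KINDS}")


@dataclass(frozen=True)
class Person:
    """An actor of the network: farmer, facilitator, researcher."""

    display_name: str
    role: str = "farmer"
    location: str | None = None

    def __post_init__(self) -> None:
        if not self.display_name:
            raise ValidationError("person display_name must be non-empty")
        if self.role not in PERSON_ROLES:
            raise ValidationError(f"person role must be one of {PERSON_ROLES}")


@dataclass(frozen=True)
class Variable:
    """What was measured; level says whether values are per-lot or per-plant."""

    name: str
    scope: str = "phenotype"
    level: str = "global"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("variable name must be non-empty")
        if self.scope not in VARIABLE_SCOPES:
            raise ValidationError(f"variable scope must be one of {VARIABLE_SCOPES}")
        if self.level not in VARIABLE_LEVELS:
            raise ValidationError(f"variable level must be one of {VARIABLE_LEVELS}")


@dataclass(frozen=True)
class Method:
    name: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("method name must be non-empty")


@dataclass(frozen=True)
class SeedLot:
    """The central traceable unit.

    ``origin_flag`` is true when the lot entered the system with no recorded
    parent (an origin of the network); lots created by events carry false.
    ``initial_quantity_g`` is ``None`` when unknown.
    """

    name: str
    germplasm_key: tuple[str, str]
    location: str
    creation_year: int
    initial_quantity_g: float | None = None
    origin_flag: bool = True
    comment: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("seed lot name must be non-empty")
        if self.initial_quantity_g is not None and self.initial_quantity_g < 0:
            raise ValidationError("initial_quantity_g must be >= 0 when known")
        if not 1900 <= self.creation_year <= 2100:
            raise ValidationError("creation_year must be a plausible year (1900-2100)")


@dataclass(frozen=True)
class Event:
    """One dated, located action linking seed lots; exactly five kinds exist."""

    event_id: str
    kind: str
    date: FlexDate
    location: str
    actor: str | None = None
    project: str | None = None
    payload: tuple[tuple[str, str], ...] = ()  # kind-specific extras, sorted key/value pairs

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"event kind must be one of {EVENT_KINDS}")

    def payload_dict(self) -> dict[str, str]:
        return dict(self.payload)


@dataclass(frozen=True)
class Relation:
    """Directed parent→child link between two seed lots, owned by one event.

    ``quantity_used_g`` is the grams taken from the parent lot; ``None``
    when unknown (common in files coming back from farms).
    """

    relation_id: int
    parent: str
    child: str
    event_id: str
    quantity_used_g: float | None = None

    def __post_init__(self) -> None:
        if self.parent == self.child:
            raise ValidationError("relation parent and child must differ")
        if self.quantity_used_g is not None and self.quantity_used_g < 0:
            raise ValidationError("quantity_used_g must be >= 0 when known")


@dataclass(frozen=True)
class RawData:
    """A measured value attached to exactly one seed lot or one relation."""

    data_id: int
    subject_kind: str  # "lot" | "relation"
    subject: str | int  # lot name or relation id
    variable: str
    method: str | None = None
    value: str = ""
    date: FlexDate | None = None
    individual_index: int | None = None

    def __post_init__(self) -> None:
        if self.subject_kind not in ("lot", "relation"):
            raise ValidationError("raw data subject must be a lot or a relation")
        if self.individual_index is not None and self.individual_index < 1:
            raise ValidationError("individual_index must be a positive integer")


@dataclass(frozen=True)
class InventoryUpdate:
    """A dated absolute stock measurement that resets the computed balance."""

    update_id: int
    lot: str
    date: FlexDate
    measured_quantity_g: float

    def __post_init__(self) -> None:
        if self.measured_quantity_g < 0:
            raise ValidationError("measured_quantity_g must be >= 0")


Entity = Union[GermplasmType, Germplasm, Location, Person, Variable, Method]


# ---------------------------------------------------------------------------
# Store
# ---------------------------------------------------------------------------


@dataclass
class Store:
    """In-memory registry with single-file sqlite persistence.

    All mutation goes through the methods below, which enforce referential
    integrity and keep the relation graph acyclic.  ``dumps()`` produces a
    canonical text serialization: two stores with the same content dump to
    byte-identical strings, which is the atomicity oracle the import layer
    relies on.
    """

    germplasm_types: dict[str, GermplasmType] = field(default_factory=dict)
    germplasms: dict[tuple[str, str], Germplasm] = field(default_factory=dict)
    locations: dict[str, Location] = field(default_factory=dict)
    persons: dict[str, Person] = field(default_factory=dict)
    variables: dict[str, Variable] = field(default_factory=dict)
    methods: dict[str, Method] = field(default_factory=dict)
    lots: dict[str, SeedLot] = field(default_factory=dict)
    events: dict[str, Event] = field(default_factory=dict)
    relations: dict[int, Relation] = field(default_factory=dict)
    raw_data: dict[int, RawData] = field(default_factory=dict)
    inventory: dict[int, InventoryUpdate] = field(default_factory=dict)
    _next_relation_id: int = 1
    _next_data_id: int = 1
    _next_update_id: int = 1
    _next_event_seq: int = 1

    # -- entity registration ------------------------------------------------

    def register(self, entity: Entity):
        """Register an entity under its natural key.

        Idempotent: re-registering an identical entity returns the same key;
        the same key with a different payload raises DuplicateKeyError.
        """
        table, key = self._table_and_key(entity)
        existing = table.get(key)
        if existing is not None:
            if existing == entity:
                return key
            raise DuplicateKeyError(f"{type(entity).__name__} {key!r} already registered with a different payload")
        if isinstance(entity, Germplasm) and entity.type_label not in self.germplasm_types:
            self.germplasm_types[entity.type_label] = GermplasmType(entity.type_label)
        if isinstance(entity, Person) and entity.location is not None and entity.location not in self.locations:
            raise ValidationError(f"person {entity.display_name!r} references unknown location {entity.location!r}")
        table[key] = entity
        return key

    def _table_and_key(self, entity: Entity):
        if isinstance(entity, GermplasmType):
            return self.germplasm_types, entity.label
        if isinstance(entity, Germplasm):
            return self.germplasms, entity.key
        if isinstance(entity, Location):
            return self.locations, entity.name
        if isinstance(entity, Person):
            return self.persons, entity.display_name
        if isinstance(entity, Variable):
            return self.variables, entity.name
        if isinstance(entity, Method):
            return self.methods, entity.name
        raise ValidationError(f"{type(entity).__name__} is not a registrable entity")

    def resolve_germplasm(self, name: str, species: str | None = None) -> Germplasm:
        """Resolve a germplasm by name, or (name, species) when ambiguous."""
        if species is not None:
            g = self.germplasms.get((name, species))
            if g is None:
                raise ValidationError(f"unknown germplasm ({name!r}, {species!r})")
            return g
        matches = [g for g in self.germplasms.values() if g.name == name]
        if not matches:
            raise ValidationError(f"unknown germplasm {name!r}")
        if len(matches) > 1:
            raise ValidationError(f"germplasm name {name!r} is ambiguous across species; give the species")
        return matches[0]

    # -- seed lots ----------------------------------------------------------

    def create_seed_lot(
        self,
        germplasm: str | Germplasm,
        location: str,
        year: int,
        initial_quantity_g: float | None = None,
        name: str | None = None,
        species: str | None = None,
        origin: bool = True,
        comment: str | None = None,
    ) -> SeedLot:
        """Create and store a seed lot; name defaults to the engine pattern."""
        g = germplasm if isinstance(germplasm, Germplasm) else self.resolve_germplasm(germplasm, species)
        if g.key not in self.germplasms:
            raise ValidationError(f"germplasm {g.key!r} is not registered")
        if location not in self.locations:
            raise ValidationError(f"location {location!r} is not registered")
        if name is None:
            from .events import name_child_lot

            name = name_child_lot(self, g.name, location, year)
        elif name in self.lots:
            raise DuplicateNameError(f"seed lot {name!r} already exists")
        lot = SeedLot(
            name=name,
            germplasm_key=g.key,
            location=location,
            creation_year=year,
            initial_quantity_g=round_grams(initial_quantity_g),
            origin_flag=origin,
            comment=comment,
        )
        self.lots[name] = lot
        return lot

    def get_lot(self, name: str) -> SeedLot:
        try:
            return self.lots[name]
        except KeyError:
            raise UnknownLotError(f"unknown seed lot {name!r}") from None

    def get_event(self, event_id: str) -> Event:
        try:
            return self.events[event_id]
        except KeyError:
            raise UnknownEventError(f"unknown event {event_id!r}") from None

    def delete_origin_lot(self, name: str) -> None:
        """Remove a lot that participates in no relation (origin cleanup)."""
        lot = self.get_lot(name)
        if any(r.parent == name or r.child == name for r in self.relations.values()):
            raise ValidationError(f"seed lot {name!r} participates in relations; delete its events instead")
        for d in [d for d in self.raw_data.values() if d.subject_kind == "lot" and d.subject == name]:
            del self.raw_data[d.data_id]
        for u in [u for u in self.inventory.values() if u.lot == name]:
            del self.inventory[u.update_id]
        del self.lots[lot.name]

    # -- events / relations -------------------------------------------------

    def next_event_id(self) -> str:
        while True:
            eid = f"E{self._next_event_seq}"
            self._next_event_seq += 1
            if eid not in self.events:
                return eid

    def add_event(self, event: Event) -> Event:
        if event.event_id in self.events:
            raise DuplicateKeyError(f"event {event.event_id!r} already exists")
        if event.location not in self.locations:
            raise ValidationError(f"event location {event.location!r} is not registered")
        if event.actor is not None and event.actor not in self.persons:
            raise ValidationError(f"event actor {event.actor!r} is not registered")
        self.events[event.event_id] = event
        return event

    def add_relation(self, parent: str, child: str, event_id: str, quantity_used_g: float | None = None) -> Relation:
        if parent not in self.lots:
            raise UnknownLotError(f"unknown parent lot {parent!r}")
        if child not in self.lots:
            raise UnknownLotError(f"unknown child lot {child!r}")
        if event_id not in self.events:
            raise UnknownEventError(f"unknown event {event_id!r}")
        if parent == child or self._reaches(child, parent):
            raise CycleError(f"relation {parent!r} -> {child!r} would create a cycle")
        rel = Relation(self._next_relation_id, parent, child, event_id, round_grams(quantity_used_g))
        self.relations[rel.relation_id] = rel
        self._next_relation_id += 1
        return rel

    def _reaches(self, start: str, target: str) -> bool:
        """Is ``target`` reachable from ``start`` along parent→child edges?"""
        if start == target:
            return True
        stack, seen = [start], {start}
        children = self.children_index()
        while stack:
            lot = stack.pop()
            for rel_id in children.get(lot, ()):
                nxt = self.relations[rel_id].child
                if nxt == target:
                    return True
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False

    def parents_index(self) -> dict[str, list[int]]:
        """child lot name -> relation ids, in insertion order."""
        idx: dict[str, list[int]] = {}
        for rel_id in sorted(self.relations):
            idx.setdefault(self.relations[rel_id].child, []).append(rel_id)
        return idx

    def children_index(self) -> dict[str, list[int]]:
        idx: dict[str, list[int]] = {}
        for rel_id in sorted(self.relations):
            idx.setdefault(self.relations[rel_id].parent, []).append(rel_id)
        return idx

    def relations_of_event(self, event_id: str) -> list[Relation]:
        return [self.relations[i] for i in sorted(self.relations) if self.relations[i].event_id == event_id]

    def to_networkx(self) -> "nx.DiGraph":
        g = nx.DiGraph()
        g.add_nodes_from(self.lots)
        for rel in self.relations.values():
            g.add_edge(rel.parent, rel.child, relation_id=rel.relation_id, event_id=rel.event_id)
        return g

    def assert_dag(self) -> None:
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise CycleError("relation graph contains a directed cycle")

    # -- raw data / inventory ------------------------------------------------

    def add_raw_data(
        self,
        subject_kind: str,
        subject: str | int,
        variable: str,
        value: str,
        method: str | None = None,
        date: FlexDate | None = None,
        individual_index: int | None = None,
    ) -> RawData:
        if subject_kind == "lot":
            if subject not in self.lots:
                raise UnknownLotError(f"unknown seed lot {subject!r}")
        elif subject_kind == "relation":
            if subject not in self.relations:
                raise ValidationError(f"unknown relation id {subject!r}")
        var = self.variables.get(variable)
        if var is None:
            raise ValidationError(f"variable {variable!r} is not registered")
        if (var.level == "individual") != (individual_index is not None):
            raise ValidationError("individual_index must be present iff the variable level is individual")
        if method is not None and method not in self.methods:
            raise ValidationError(f"method {method!r} is not registered")
        rd = RawData(self._next_data_id, subject_kind, subject, variable, method, value, date, individual_index)
        self.raw_data[rd.data_id] = rd
        self._next_data_id += 1
        return rd

    def add_inventory(self, lot: str, date: FlexDate, measured_quantity_g: float) -> InventoryUpdate:
        if lot not in self.lots:
            raise UnknownLotError(f"unknown seed lot {lot!r}")
        upd = InventoryUpdate(self._next_update_id, lot, date, round_grams(measured_quantity_g))
        self.inventory[upd.update_id] = upd
        self._next_update_id += 1
        return upd

    # -- integrity / copy ----------------------------------------------------

    def validate_integrity(self) -> None:
        """Every reference resolves and the relation graph is a DAG."""
        for lot in self.lots.values():
            if lot.germplasm_key not in self.germplasms:
                raise ValidationError(f"lot {lot.name!r} references unknown germplasm {lot.germplasm_key!r}")
            if lot.location not in self.locations:
                raise ValidationError(f"lot {lot.name!r} references unknown location {lot.location!r}")
        for rel in self.relations.values():
            if rel.parent not in self.lots or rel.child not in self.lots:
                raise ValidationError(f"relation {rel.relation_id} references a missing lot")
            if rel.event_id not in self.events:
                raise ValidationError(f"relation {rel.relation_id} references missing event {rel.event_id!r}")
        for rd in self.raw_data.values():
            if rd.subject_kind == "lot" and rd.subject not in self.lots:
                raise ValidationError(f"raw data {rd.data_id} references missing lot {rd.subject!r}")
            if rd.subject_kind == "relation" and rd.subject not in self.relations:
                raise ValidationError(f"raw data {rd.data_id} references missing relation {rd.subject!r}")
            if rd.variable not in self.variables:
                raise ValidationError(f"raw data {rd.data_id} references missing variable {rd.variable!r}")
        for upd in self.inventory.values():
            if upd.lot not in self.lots:
                raise ValidationError(f"inventory update {upd.update_id} references missing lot {upd.lot!r}")
        self.assert_dag()

    def snapshot(self) -> "Store":
        """Deep copy used for two-phase (atomic) file imports."""
        return copy.deepcopy(self)

    def restore(self, other: "Store") -> None:
        """Adopt the full state of ``other`` (the committed snapshot)."""
        for f in (
            "germplasm_types",
            "germplasms",
            "locations",
            "persons",
            "variables",
            "methods",
            "lots",
            "events",
            "relations",
            "raw_data",
            "inventory",
        ):
            setattr(self, f, getattr(other, f))
        self._next_relation_id = other._next_relation_id
        self._next_data_id = other._next_data_id
        self._next_update_id = other._next_update_id
        self._next_event_seq = other._next_event_seq

    # -- serialization -------------------------------------------------------

    def dumps(self) -> str:
        """Canonical JSON dump: equal content ⇒ byte-identical text."""

        def dt(d: FlexDate | None):
            return None if d is None else d.isoformat()

        doc = {
            "germplasm_types": [{"label": t.label} for t in sorted(self.germplasm_types.values(), key=lambda t: t.label)],
            "germplasms": [
                {"name": g.name, "species": g.species, "type": g.type_label}
                for g in sorted(self.germplasms.values(), key=lambda g: g.key)
            ],
            "locations": [
                {"name": l.name, "kind": l.kind, "region": l.region}
                for l in sorted(self.locations.values(), key=lambda l: l.name)
            ],
            "persons": [
                {"name": p.display_name, "role": p.role, "location": p.location}
                for p in sorted(self.persons.values(), key=lambda p: p.display_name)
            ],
            "variables": [
                {"name": v.name, "scope": v.scope, "level": v.level}
                for v in sorted(self.variables.values(), key=lambda v: v.name)
            ],
            "methods": [
                {"name": m.name, "description": m.description}
                for m in sorted(self.methods.values(), key=lambda m: m.name)
            ],
            "lots": [
                {
                    "name": l.name,
                    "germplasm": list(l.germplasm_key),
                    "location": l.location,
                    "year": l.creation_year,
                    "initial_g": l.initial_quantity_g,
                    "origin": l.origin_flag,
                    "comment": l.comment,
                }
                for l in sorted(self.lots.values(), key=lambda l: l.name)
            ],
            "events": [
                {
                    "id": e.event_id,
                    "kind": e.kind,
                    "date": dt(e.date),
                    "location": e.location,
                    "actor": e.actor,
                    "project": e.project,
                    "payload": list(e.payload),
                }
                for e in sorted(self.events.values(), key=lambda e: e.event_id)
            ],
            "relations": [
                {
                    "id": r.relation_id,
                    "parent": r.parent,
                    "child": r.child,
                    "event": r.event_id,
                    "quantity_g": r.quantity_used_g,
                }
                for r in sorted(self.relations.values(), key=lambda r: r.relation_id)
            ],
            "raw_data": [
                {
                    "id": d.data_id,
                    "subject_kind": d.subject_kind,
                    "subject": d.subject,
                    "variable": d.variable,
                    "method": d.method,
                    "value": d.value,
                    "date": dt(d.date),
                    "individual": d.individual_index,
                }
                for d in sorted(self.raw_data.values(), key=lambda d: d.data_id)
            ],
            "inventory": [
                {"id": u.update_id, "lot": u.lot, "date": dt(u.date), "measured_g": u.measured_quantity_g}
                for u in sorted(self.inventory.values(), key=lambda u: u.update_id)
            ],
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":"), ensure_ascii=False)

    # sqlite persistence ----------------------------------------------------

    _SCHEMA = """
    CREATE TABLE germplasm_type (label TEXT PRIMARY KEY);
    CREATE TABLE germplasm (name TEXT, species TEXT, type_label TEXT, PRIMARY KEY (name, species));
    CREATE TABLE location (name TEXT PRIMARY KEY, kind TEXT, region TEXT);
    CREATE TABLE person (display_name TEXT PRIMARY KEY, role TEXT, location TEXT);
    CREATE TABLE variable (name TEXT PRIMARY KEY, scope TEXT, level TEXT);
    CREATE TABLE method (name TEXT PRIMARY KEY, description TEXT);
    CREATE TABLE seed_lot (name TEXT PRIMARY KEY, germplasm_name TEXT, germplasm_species TEXT,
                           location TEXT, creation_year INTEGER, initial_quantity_g REAL,
                           origin_flag INTEGER, comment TEXT);
    CREATE TABLE event (event_id TEXT PRIMARY KEY, kind TEXT, date TEXT, location TEXT,
                        actor TEXT, project TEXT, payload TEXT);
    CREATE TABLE relation (relation_id INTEGER PRIMARY KEY, parent TEXT, child TEXT,
                           event_id TEXT, quantity_used_g REAL);
    CREATE TABLE raw_data (data_id INTEGER PRIMARY KEY, subject_kind TEXT, subject TEXT,
                           variable TEXT, method TEXT, value TEXT, date TEXT, individual_index INTEGER);
    CREATE TABLE update_quantity (update_id INTEGER PRIMARY KEY, lot TEXT, date TEXT, measured_quantity_g REAL);
    CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
    """

    def save(self, path: str | Path) -> None:
        """Write the whole store to a single-file sqlite database."""
        path = Path(path)
        if path.exists():
            path.unlink()
        con = sqlite3.connect(path)
        try:
            con.executescript(self._SCHEMA)
            con.executemany("INSERT INTO germplasm_type VALUES (?)", [(t.label,) for t in self.germplasm_types.values()])
            con.executemany(
                "INSERT INTO germplasm VALUES (?,?,?)",
                [(g.name, g.species, g.type_label) for g in self.germplasms.values()],
            )
            con.executemany(
                "INSERT INTO location VALUES (?,?,?)", [(l.name, l.kind, l.region) for l in self.locations.values()]
            )
            con.executemany(
                "INSERT INTO person VALUES (?,?,?)",
                [(p.display_name, p.role, p.location) for p in self.persons.values()],
            )
            con.executemany(
                "INSERT INTO variable VALUES (?,?,?)", [(v.name, v.scope, v.level) for v in self.variables.values()]
            )
            con.executemany(
                "INSERT INTO method VALUES (?,?)", [(m.name, m.description) for m in self.methods.values()]
            )
            con.executemany(
                "INSERT INTO seed_lot VALUES (?,?,?,?,?,?,?,?)",
                [
                    (
                        l.name,
                        l.germplasm_key[0],
                        l.germplasm_key[1],
                        l.location,
                        l.creation_year,
                        l.initial_quantity_g,
                        int(l.origin_flag),
                        l.comment,
                    )
                    for l in self.lots.values()
                ],
            )
            con.executemany(
                "INSERT INTO event VALUES (?,?,?,?,?,?,?)",
                [
                    (e.event_id, e.kind, e.date.isoformat(), e.location, e.actor, e.project, json.dumps(list(e.payload)))
                    for e in self.events.values()
                ],
            )
            con.executemany(
                "INSERT INTO relation VALUES (?,?,?,?,?)",
                [(r.relation_id, r.parent, r.child, r.event_id, r.quantity_used_g) for r in self.relations.values()],
            )
            con.executemany(
                "INSERT INTO raw_data VALUES (?,?,?,?,?,?,?,?)",
                [
                    (
                        d.data_id,
                        d.subject_kind,
                        str(d.subject),
                        d.variable,
                        d.method,
                        d.value,
                        None if d.date is None else d.date.isoformat(),
                        d.individual_index,
                    )
                    for d in self.raw_data.values()
                ],
            )
            con.executemany(
                "INSERT INTO update_quantity VALUES (?,?,?,?)",
                [(u.update_id, u.lot, u.date.isoformat(), u.measured_quantity_g) for u in self.inventory.values()],
            )
            con.executemany(
                "INSERT INTO meta VALUES (?,?)",
                [
                    ("next_relation_id", str(self._next_relation_id)),
                    ("next_data_id", str(self._next_data_id)),
                    ("next_update_id", str(self._next_update_id)),
                    ("next_event_seq", str(self._next_event_seq)),
                ],
            )
            con.commit()
        finally:
            con.close()

    @classmethod
    def load(cls, path: str | Path) -> "Store":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"store file {path} does not exist")
        con = sqlite3.connect(path)
        try:
            store = cls()
            for (label,) in con.execute("SELECT label FROM germplasm_type ORDER BY rowid"):
                store.germplasm_types[label] = GermplasmType(label)
            for name, species, tl in con.execute("SELECT * FROM germplasm ORDER BY rowid"):
                store.germplasms[(name, species)] = Germplasm(name, species, tl)
            for name, kind, region in con.execute("SELECT * FROM location ORDER BY rowid"):
                store.locations[name] = Location(name, kind, region)
            for name, role, loc in con.execute("SELECT * FROM person ORDER BY rowid"):
                store.persons[name] = Person(name, role, loc)
            for name, scope, level in con.execute("SELECT * FROM variable ORDER BY rowid"):
                store.variables[name] = Variable(name, scope, level)
            for name, desc in con.execute("SELECT * FROM method ORDER BY rowid"):
                store.methods[name] = Method(name, desc)
            for row in con.execute("SELECT * FROM seed_lot ORDER BY rowid"):
                name, gname, gspecies, loc, year, init, origin, comment = row
                store.lots[name] = SeedLot(name, (gname, gspecies), loc, year, init, bool(origin), comment)
            for row in con.execute("SELECT * FROM event ORDER BY rowid"):
                eid, kind, date, loc, actor, project, payload = row
                store.events[eid] = Event(
                    eid,
                    kind,
                    _parse_stored_date(date),
                    loc,
                    actor,
                    project,
                    tuple(tuple(p) for p in json.loads(payload)),
                )
            for rid, parent, child, eid, qty in con.execute("SELECT * FROM relation ORDER BY relation_id"):
                store.relations[rid] = Relation(rid, parent, child, eid, qty)
            for row in con.execute("SELECT * FROM raw_data ORDER BY data_id"):
                did, skind, subject, var, method, value, date, idx = row
                subj: str | int = int(subject) if skind == "relation" else subject
                store.raw_data[did] = RawData(
                    did, skind, subj, var, method, value, None if date is None else _parse_stored_date(date), idx
                )
            for uid, lot, date, qty in con.execute("SELECT * FROM update_quantity ORDER BY update_id"):
                store.inventory[uid] = InventoryUpdate(uid, lot, _parse_stored_date(date), qty)
            meta = dict(con.execute("SELECT key, value FROM meta"))
            store._next_relation_id = int(meta.get("next_relation_id", 1))
            store._next_data_id = int(meta.get("next_data_id", 1))
            store._next_update_id = int(meta.get("next_update_id", 1))
            store._next_event_seq = int(meta.get("next_event_seq", 1))
            return store
        finally:
            con.close()


def _parse_stored_date(text: str) -> FlexDate:
    parts = text.split("-")
    if len(parts) == 1:
        return FlexDate(int(parts[0]))
    return FlexDate(int(parts[0]), int(parts[1]), int(parts[2]))
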