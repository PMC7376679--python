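"""Event engine: create typed events with correct parent multiplicity and
auto-create the resulting child seed lots.

Multiplicity per kind — reproduction: 1 parent, cross: exactly 2 (mother,
father), selection: 1 parent (one child per selection label), mixture: >= 2,
diffusion: 1.  Every event except a multi-label selection yields exactly one
child lot.  Multi-step composition builds arbitrary crossing schemes: a
backcross is AxB -> C then CxB; a polycross is AxB -> C, DxE -> F, then FxC.
An open-pollinated event among several parents is recorded as a mixture.

The child lot inherits its germplasm from the parent for reproduction,
selection and diffusion; a cross registers a new germplasm named
"<mother> x <father>", and a mixture derives one from the sorted parent
germplasm names (a mixture is a new genetic entity) unless a name is given.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .dates import FlexDate
from .errors import (
    MultiplicityError,
    UnknownParentError,
    UnknownRecipientError,
    ValidationError,
)
from .model import EVENT_KINDS, Event, Germplasm, Relation, SeedLot, Store, round_grams

_MULTIPLICITY = {"reproduction": (1, 1), "cross": (2, 2), "selection": (1, 1), "mixture": (2, None), "diffusion": (1, 1)}


@dataclass
class EventSpec:
    """Declarative description of one event before it is recorded.

    ``parents`` pairs each parent lot name with the grams taken from it
    (``None`` = unknown: allowed, recorded as unknown, the stock ledger is
    left untouched and a warning is emitted — files from farms are often
    incomplete).
    """

    kind: str
    date: FlexDate
    location: str
    parents: list[tuple[str, float | None]]
    actor: str | None = None
    project: str | None = None
    event_id: str | None = None
    # kind-specific payload
    mother: str | None = None  # cross: which parent lot is the mother
    father: str | None = None
    selection_labels: list[tuple[str, float | None]] = field(default_factory=list)  # (label, grams used)
    recipient_location: str | None = None  # diffusion
    recipient_person: str | None = None
    mixture_name: str | None = None  # explicit germplasm name for the blend
    plot: str | None = None  # reproduction: plot/block free text
    harvest_date: FlexDate | None = None  # reproduction
    harvested_quantity_g: float | None = None  # becomes the child's initial stock
    child_name: str | None = None
    child_year: int | None = None  # default: event (or harvest) year


@dataclass
class EventResult:
    event: Event
    children: list[SeedLot]
    relations: list[Relation]
    warnings: list[str] = field(default_factory=list)


def name_child_lot(store: Store, germplasm_name: str, location_name: str, year: int) -> str:
    """Deterministic child-lot name: ``<germplasm>_<location>_<year>``.

    "_" inside a component is mapped to "-" so the pattern stays parseable;
    collisions get a ``_<n>`` suffix (n >= 2).
    """
    base = "_".join((_escape(germplasm_name), _escape(location_name), str(year)))
    if base not in store.lots:
        return base
    n = 2
    while f"{base}_{n}" in store.lots:
        n += 1
    return f"{base}_{n}"


def _escape(component: str) -> str:
    return re.sub(r"\s+", " ", component.strip()).replace("_", "-")


def record_event(store: Store, spec: EventSpec) -> EventResult:
    """Validate the spec, store the event, create relations and child lots.

    All checks run before any mutation, so a raised error leaves the store
    untouched.
    """
    if spec.kind not in EVENT_KINDS:
        raise ValidationError(f"unknown event kind {spec.kind!r}; expected one of {EVENT_KINDS}")
    lo, hi = _MULTIPLICITY[spec.kind]
    if len(spec.parents) < lo or (hi is not None and len(spec.parents) > hi):
        bound = f"exactly {lo}" if lo == hi else f"at least {lo}"
        raise MultiplicityError(f"{spec.kind} takes {bound} parent(s), got {len(spec.parents)}")
    for name, _ in spec.parents:
        if name not in store.lots:
            raise UnknownParentError(f"unknown parent lot {name!r}")
    if len({name for name, _ in spec.parents}) != len(spec.parents):
        raise ValidationError("duplicate parent lot in event")
    if spec.location not in store.locations:
        raise ValidationError(f"event location {spec.location!r} is not registered")

    warnings: list[str] = []
    payload: dict[str, str] = {}
    if spec.plot:
        payload["plot"] = spec.plot
    if spec.harvest_date is not None:
        payload["harvest_date"] = spec.harvest_date.isoformat()
    if spec.harvested_quantity_g is not None:
        payload["harvested_quantity_g"] = f"{round_grams(spec.harvested_quantity_g):g}"

    event_location = spec.location
    child_location = spec.location
    parents = list(spec.parents)

    if spec.kind == "cross":
        mother_name, father_name = _mother_father(spec)
        parents = [p for p in spec.parents if p[0] == mother_name] + [p for p in spec.parents if p[0] == father_name]
        payload["mother"] = mother_name
        payload["father"] = father_name
    elif spec.kind == "selection":
        labels = spec.selection_labels or [("sel", spec.parents[0][1])]
        if len({lab for lab, _ in labels}) != len(labels):
            raise ValidationError("selection labels must be distinct")
        payload["labels"] = "|".join(lab for lab, _ in labels)
    elif spec.kind == "diffusion":
        if spec.recipient_location is None:
            raise UnknownRecipientError("diffusion requires a recipient location")
        if spec.recipient_location not in store.locations:
            raise UnknownRecipientError(f"unknown recipient location {spec.recipient_location!r}")
        if spec.recipient_person is not None and spec.recipient_person not in store.persons:
            raise UnknownRecipientError(f"unknown recipient person {spec.recipient_person!r}")
        parent_lot = store.get_lot(spec.parents[0][0])
        same_place = spec.recipient_location == parent_lot.location
        same_person = spec.recipient_person is None or spec.recipient_person == spec.actor
        if same_place and same_person:
            raise ValidationError("diffusion recipient must differ from the lot's current location or holder")
        child_location = spec.recipient_location
        payload["recipient_location"] = spec.recipient_location
        if spec.recipient_person:
            payload["recipient_person"] = spec.recipient_person

    child_germplasm = _child_germplasm(store, spec)
    child_year = spec.child_year
    if child_year is None:
        child_year = spec.harvest_date.year if (spec.kind == "reproduction" and spec.harvest_date) else spec.date.year

    # ---- mutation phase --------------------------------------------------
    event_id = spec.event_id or store.next_event_id()
    event = Event(
        event_id=event_id,
        kind=spec.kind,
        date=spec.date,
        location=event_location,
        actor=spec.actor,
        project=spec.project,
        payload=tuple(sorted(payload.items())),
    )
    store.add_event(event)
    if child_germplasm.key not in store.germplasms:
        store.register(child_germplasm)

    children: list[SeedLot] = []
    relations: list[Relation] = []
    if spec.kind == "selection":
        labels = spec.selection_labels or [("sel", spec.parents[0][1])]
        for label, qty in labels:
            child = store.create_seed_lot(
                child_germplasm,
                child_location,
                child_year,
                initial_quantity_g=None,
                name=spec.child_name if len(labels) == 1 else None,
                origin=False,
                comment=f"selection {label!r}",
            )
            rel = store.add_relation(spec.parents[0][0], child.name, event_id, qty)
            children.append(child)
            relations.append(rel)
            if qty is None:
                warnings.append(f"unknown quantity for selection label {label!r}; parent ledger untouched")
    else:
        initial = None
        if spec.kind == "reproduction":
            initial = spec.harvested_quantity_g
        elif spec.kind == "diffusion":
            initial = spec.parents[0][1]
        elif spec.kind == "mixture":
            quantities = [q for _, q in spec.parents]
            if all(q is not None for q in quantities):
                initial = sum(quantities)
        child = store.create_seed_lot(
            child_germplasm,
            child_location,
            child_year,
            initial_quantity_g=initial,
            name=spec.child_name,
            origin=False,
        )
        children.append(child)
        for pname, qty in parents:
            rel = store.add_relation(pname, child.name, event_id, qty)
            relations.append(rel)
            if qty is None:
                warnings.append(f"unknown quantity taken from {pname!r}; parent ledger untouched")
    return EventResult(event=event, children=children, relations=relations, warnings=warnings)


def _mother_father(spec: EventSpec) -> tuple[str, str]:
    names = [name for name, _ in spec.parents]
    mother = spec.mother if spec.mother is not None else names[0]
    father = spec.father if spec.father is not None else next(n for n in names if n != mother)
    if mother not in names or father not in names or mother == father:
        raise ValidationError("cross mother/father must designate the two distinct parent lots")
    return mother, father


def _child_germplasm(store: Store, spec: EventSpec) -> Germplasm:
    parent_germplasms = [store.germplasms[store.get_lot(name).germplasm_key] for name, _ in spec.parents]
    if spec.kind in ("reproduction", "selection", "diffusion"):
        return parent_germplasms[0]
    if spec.kind == "cross":
        mother, father = _mother_father(spec)
        gm = store.germplasms[store.get_lot(mother).germplasm_key]
        gf = store.germplasms[store.get_lot(father).germplasm_key]
        # mother written first, mirroring the AxB naming convention
        return Germplasm(f"{gm.name} x {gf.name}", gm.species, gm.type_label)
    # mixture: a blend is a new genetic entity
    names = sorted({g.name for g in parent_germplasms})
    name = spec.mixture_name or " + ".join(names)
    species = parent_germplasms[0].species
    return Germplasm(name, species, parent_germplasms[0].type_label)


def record_diffusion(
    store: Store,
    lot: str,
    recipient_location: str,
    recipient_person: str | None,
    quantity_g: float | None,
    date: FlexDate,
    actor: str | None = None,
    event_id: str | None = None,
) -> EventResult:
    """Convenience wrapper: move ``quantity_g`` of ``lot`` to a recipient.

    The child lot is created at the recipient location with the same
    germplasm; the parent's ledger is debited by ``quantity_g`` (no debit
    and a warning when the quantity is unknown).
    """
    parent = store.get_lot(lot)
    spec = EventSpec(
        kind="diffusion",
        date=date,
        location=parent.location,
        parents=[(lot, quantity_g)],
        actor=actor,
        recipient_location=recipient_location,
        recipient_person=recipient_person,
        event_id=event_id,
    )
    return record_event(store, spec)
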