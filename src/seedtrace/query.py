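"""Filtered data retrieval, card assembly and prefix search.

A data query returns exactly three tables — measures attached to seed
lots, global measures attached to relations, and individual-level
measures — all with the uniform columns (subject, variable, method, date,
value, level, individual_index).  Filters are conjunctive; strengthening a
filter can only shrink each table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dates import FlexDate
from .errors import UnknownRelationError
from .ledger import LedgerEntry, current_stock, stock_history
from .model import RawData, Relation, Store

DATA_COLUMNS = ("subject", "variable", "method", "date", "value", "level", "individual_index")


@dataclass
class DataTable:
    header: tuple[str, ...]
    rows: list[tuple[str, ...]] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["\t".join(self.header)]
        lines.extend("\t".join(row) for row in self.rows)
        return "\n".join(lines) + "\n"

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class QueryFilter:
    """Conjunctive criteria; every field is optional."""

    germplasm: str | None = None
    species: str | None = None
    location: str | None = None
    actor: str | None = None
    variable: str | None = None
    project: str | None = None
    date_range: tuple[FlexDate, FlexDate] | None = None

    def __post_init__(self) -> None:
        if self.date_range is not None:
            start, end = self.date_range
            if end.sort_key() < start.sort_key():
                raise ValueError("date_range end precedes start")


@dataclass
class QueryResult:
    """The three result tables of a data query."""

    seed_lot_table: DataTable
    relation_table: DataTable
    individual_table: DataTable

    def tables(self) -> tuple[DataTable, DataTable, DataTable]:
        return (self.seed_lot_table, self.relation_table, self.individual_table)


@dataclass
class SeedLotCard:
    """Aggregated view of one lot: identity, history, data, stock."""

    identity: dict[str, str]
    history: dict[str, list[str]]  # "created_by": 0-1 entries, "used_in": n entries
    data: DataTable
    stock: tuple[float | None, list[LedgerEntry], list[str]]  # current, ledger, warnings

    def sections(self) -> tuple:
        return (self.identity, self.history, self.data, self.stock)

    def to_tsv(self) -> dict[str, str]:
        identity = "\n".join(f"{k}\t{v}" for k, v in self.identity.items()) + "\n"
        history_lines = [f"created_by\t{line}" for line in self.history["created_by"]] or ["created_by\tno creating event"]
        history_lines += [f"used_in\t{line}" for line in self.history["used_in"]]
        current, entries, warnings = self.stock
        stock_lines = ["date\tkind\tamount_g\tbalance_after_g\tsource"]
        stock_lines += [
            f"{e.date.isoformat()}\t{e.kind}\t{e.amount_g:g}\t{e.balance_after_g:g}\t{e.source}" for e in entries
        ]
        stock_lines.append(f"current\t{'' if current is None else f'{current:g}'}\t{'; '.join(warnings)}")
        return {
            "identity": identity,
            "history": "\n".join(history_lines) + "\n",
            "data": self.data.to_tsv(),
            "stock": "\n".join(stock_lines) + "\n",
        }


@dataclass
class RelationCard:
    """Aggregated view of one parent→child link: info, then data."""

    info: list[dict[str, str]]  # one entry per relation for the pair, newest first
    data: dict[str, DataTable]  # {"global": ..., "individual": ...}

    def sections(self) -> tuple:
        return (self.info, self.data)

    def to_tsv(self) -> dict[str, str]:
        info_lines = ["parent\tchild\tevent\tkind\tdate\tquantity_g"]
        for entry in self.info:
            info_lines.append(
                "\t".join(entry[k] for k in ("parent", "child", "event", "kind", "date", "quantity_g"))
            )
        return {
            "info": "\n".join(info_lines) + "\n",
            "data_global": self.data["global"].to_tsv(),
            "data_individual": self.data["individual"].to_tsv(),
        }


# ---------------------------------------------------------------------------


def _measure_context(store: Store, rd: RawData):
    """(lot, event, date) context a measure is judged against."""
    if rd.subject_kind == "relation":
        rel = store.relations[rd.subject]
        event = store.events[rel.event_id]
        lot = store.lots[rel.child]
        date = rd.date or event.date
        return lot, event, date
    lot = store.lots[rd.subject]
    creating = [store.relations[r] for r in store.parents_index().get(lot.name, [])]
    event = store.events[creating[0].event_id] if creating else None
    date = rd.date or (event.date if event else None)
    return lot, event, date


def _matches(store: Store, rd: RawData, filt: QueryFilter) -> bool:
    lot, event, date = _measure_context(store, rd)
    germplasm = store.germplasms[lot.germplasm_key]
    if filt.variable is not None and rd.variable != filt.variable:
        return False
    if filt.germplasm is not None and germplasm.name != filt.germplasm:
        return False
    if filt.species is not None and germplasm.species != filt.species:
        return False
    if filt.location is not None:
        loc = event.location if event is not None else lot.location
        if loc != filt.location and lot.location != filt.location:
            return False
    if filt.actor is not None and (event is None or event.actor != filt.actor):
        return False
    if filt.project is not None and (event is None or event.project != filt.project):
        return False
    if filt.date_range is not None:
        start, end = filt.date_range
        if date is None or not (start.sort_key() <= date.sort_key() <= end.sort_key()):
            return False
    return True


def _row(store: Store, rd: RawData) -> tuple[str, ...]:
    if rd.subject_kind == "relation":
        rel = store.relations[rd.subject]
        subject = f"{rel.parent} -> {rel.child}"
    else:
        subject = str(rd.subject)
    level = store.variables[rd.variable].level
    return (
        subject,
        rd.variable,
        rd.method or "",
        rd.date.isoformat() if rd.date else "",
        rd.value,
        level,
        str(rd.individual_index) if rd.individual_index is not None else "",
    )


def query_data(store: Store, filt: QueryFilter | None = None) -> QueryResult:
    """Route every matching measure into the three result tables."""
    filt = filt or QueryFilter()
    result = QueryResult(DataTable(DATA_COLUMNS), DataTable(DATA_COLUMNS), DataTable(DATA_COLUMNS))
    for did in sorted(store.raw_data):
        rd = store.raw_data[did]
        if not _matches(store, rd, filt):
            continue
        row = _row(store, rd)
        if rd.individual_index is not None:
            result.individual_table.rows.append(row)
        elif rd.subject_kind == "lot":
            result.seed_lot_table.rows.append(row)
        else:
            result.relation_table.rows.append(row)
    return result


def _event_line(store: Store, rel: Relation) -> str:
    event = store.events[rel.event_id]
    return f"{event.kind} {event.event_id} ({event.date.isoformat()}) {rel.parent} -> {rel.child}"


def seed_lot_card(store: Store, lot_name: str) -> SeedLotCard:
    lot = store.get_lot(lot_name)
    germplasm = store.germplasms[lot.germplasm_key]
    identity = {
        "name": lot.name,
        "species": germplasm.species,
        "germplasm": germplasm.name,
        "germplasm_type": germplasm.type_label,
        "location": lot.location,
        "creation_year": str(lot.creation_year),
        "origin": "yes" if lot.origin_flag else "no",
    }
    creating = [store.relations[r] for r in store.parents_index().get(lot.name, [])]
    using = [store.relations[r] for r in store.children_index().get(lot.name, [])]
    history = {
        "created_by": [_event_line(store, r) for r in creating],
        "used_in": [_event_line(store, r) for r in using],
    }
    data = DataTable(DATA_COLUMNS)
    for did in sorted(store.raw_data):
        rd = store.raw_data[did]
        if rd.subject_kind == "lot" and rd.subject == lot.name:
            data.rows.append(_row(store, rd))
    entries, warnings = stock_history(store, lot.name)
    current, _ = current_stock(store, lot.name)
    return SeedLotCard(identity=identity, history=history, data=data, stock=(current, entries, warnings))


def relation_card(store: Store, parent: str, child: str) -> RelationCard:
    store.get_lot(parent)
    store.get_lot(child)
    rels = [r for r in store.relations.values() if r.parent == parent and r.child == child]
    if not rels:
        raise UnknownRelationError(f"no relation links {parent!r} to {child!r}")
    # newest first when repeated events share the pair
    rels.sort(key=lambda r: (store.events[r.event_id].date.sort_key(), r.relation_id), reverse=True)
    info = []
    for rel in rels:
        event = store.events[rel.event_id]
        info.append(
            {
                "parent": rel.parent,
                "child": rel.child,
                "event": event.event_id,
                "kind": event.kind,
                "date": event.date.isoformat(),
                "quantity_g": "" if rel.quantity_used_g is None else f"{rel.quantity_used_g:g}",
            }
        )
    rel_ids = {r.relation_id for r in rels}
    data_global = DataTable(DATA_COLUMNS)
    data_individual = DataTable(DATA_COLUMNS)
    for did in sorted(store.raw_data):
        rd = store.raw_data[did]
        attached = (rd.subject_kind == "relation" and rd.subject in rel_ids) or (
            rd.subject_kind == "lot" and rd.subject == child
        )
        if not attached:
            continue
        (data_individual if rd.individual_index is not None else data_global).rows.append(_row(store, rd))
    return RelationCard(info=info, data={"global": data_global, "individual": data_individual})


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchHit:
    kind: str  # "seed_lot" | "germplasm" | "relation"
    name: str
    rank: int  # 0 exact, 1 prefix, 2 substring


def search(store: Store, prefix: str) -> list[SearchHit]:
    """Case-insensitive auto-complete over lots, germplasms and relations.

    Ranking: exact match first, then prefix matches, then substring
    matches; ties alphabetical.
    """
    if not prefix:
        return []
    needle = prefix.lower()
    candidates: list[tuple[str, str]] = [("seed_lot", name) for name in store.lots]
    candidates += [("germplasm", g.name) for g in store.germplasms.values()]
    candidates += [("relation", f"{r.parent} -> {r.child}") for r in store.relations.values()]
    hits = []
    seen = set()
    for kind, name in candidates:
        key = (kind, name)
        if key in seen:
            continue
        seen.add(key)
        lowered = name.lower()
        if lowered == needle:
            rank = 0
        elif lowered.startswith(needle):
            rank = 1
        elif needle in lowered:
            rank = 2
        else:
            continue
        hits.append(SearchHit(kind, name, rank))
    hits.sort(key=lambda h: (h.rank, h.name.lower(), h.kind))
    return hits
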