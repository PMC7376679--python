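"""Import, export and delete-by-file for the six tabulated formats.

Imports are two-phase and atomic: a full validation/apply pass runs against
a snapshot of the store collecting every issue, and the snapshot is adopted
only when no error was found.  A rejected import therefore leaves the store
byte-identical.  Unknown parent lots, missing mandatory headers and
multiplicity violations are errors; unknown quantities and unregistered
variables (auto-registered) are warnings.

Encoding is UTF-8, the separator is a tab, and an empty cell means
*missing* — never zero.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from .dates import FlexDate, parse_date
from .errors import (
    DateParseError,
    FormatError,
    IncompatibleSelectionError,
    SeedTraceError,
    UnknownEventError,
)
from .events import EventSpec, record_event
from .formats import (
    FileFormatSpec,
    VariableColumn,
    format_spec,
    parse_variable_column,
    apply_remap,
    reverse_remap,
)
from .lineage import DeletionReport, delete_event
from .model import Relation, SeedLot, Store, Variable


@dataclass
class Issue:
    row: int  # 1-based file line number; 1 is the header row
    severity: str  # "error" | "warning"
    message: str


@dataclass
class ImportReport:
    """Outcome of one file submission.

    ``status`` is ``rejected`` iff at least one error was found, in which
    case nothing was inserted.
    """

    kind: str
    status: str = "ok"
    rows_read: int = 0
    events_created: int = 0
    lots_created: int = 0
    data_points_created: int = 0
    issues: list[Issue] = field(default_factory=list)

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warning"]

    def render_text(self) -> str:
        head = (
            f"{self.kind} file: {self.status} — rows {self.rows_read}, "
            f"events {self.events_created}, lots {self.lots_created}, data {self.data_points_created}"
        )
        lines = [head] + [f"row {i.row}\t{i.severity}\t{i.message}" for i in self.issues]
        return "\n".join(lines)

    def render_machine(self) -> str:
        """One issue per line: row<TAB>severity<TAB>message."""
        return "\n".join(f"{i.row}\t{i.severity}\t{i.message}" for i in self.issues)


def _read_rows(source: str | IO[str]) -> list[list[str]]:
    text = source if isinstance(source, str) else source.read()
    return [row for row in csv.reader(_io.StringIO(text), delimiter="\t")]


def _parse_quantity(cell: str | None, row: int, col: str, issues: list[Issue]) -> tuple[float | None, bool]:
    """Returns (value, ok). Empty cell = unknown quantity (warning)."""
    if cell is None or cell.strip() == "":
        issues.append(Issue(row, "warning", f"unknown quantity in column {col!r}"))
        return None, True
    try:
        value = float(cell)
    except ValueError:
        issues.append(Issue(row, "error", f"column {col!r}: {cell!r} is not a number"))
        return None, False
    if value < 0:
        issues.append(Issue(row, "error", f"column {col!r}: quantity must be >= 0"))
        return None, False
    return value, True


def _parse_row_date(cell: str | None, row: int, col: str, issues: list[Issue], required: bool = True) -> FlexDate | None:
    if cell is None or cell.strip() == "":
        if required:
            issues.append(Issue(row, "error", f"missing date in column {col!r}"))
        return None
    try:
        return parse_date(cell)
    except DateParseError as exc:
        issues.append(Issue(row, "error", f"column {col!r}: {exc}"))
        return None


class _Importer:
    """Applies one parsed file to a snapshot store, collecting issues."""

    def __init__(self, snapshot: Store, spec: FileFormatSpec, var_columns: list[VariableColumn]):
        self.store = snapshot
        self.spec = spec
        self.var_columns = var_columns
        self.issues: list[Issue] = []
        self.events_created = 0
        self.lots_created = 0
        self.data_created = 0
        self._registered_vars: set[str] = set()

    # -- shared helpers -----------------------------------------------------

    def ensure_location(self, name: str | None, row: int) -> str | None:
        if name is None or not name.strip():
            return None
        name = name.strip()
        if name not in self.store.locations:
            from .model import Location

            self.store.register(Location(name))
            self.issues.append(Issue(row, "warning", f"location {name!r} auto-registered"))
        return name

    def ensure_person(self, name: str | None, row: int) -> str | None:
        if name is None or not name.strip():
            return None
        name = name.strip()
        if name not in self.store.persons:
            from .model import Person

            self.store.register(Person(name))
            self.issues.append(Issue(row, "warning", f"person {name!r} auto-registered"))
        return name

    def ensure_variable(self, col: VariableColumn, level: str, row: int) -> None:
        if col.variable in self.store.variables:
            return
        self.store.register(Variable(col.variable, scope="phenotype", level=level))
        if col.variable not in self._registered_vars:
            self._registered_vars.add(col.variable)
            self.issues.append(Issue(row, "warning", f"variable {col.variable!r} auto-registered ({level})"))

    def ensure_method(self, name: str | None) -> None:
        if name and name not in self.store.methods:
            from .model import Method

            self.store.register(Method(name))

    def skip_if_existing_event(self, event_id: str | None, row: int) -> bool:
        if event_id and event_id in self.store.events:
            self.issues.append(Issue(row, "warning", f"event {event_id!r} already recorded; row skipped"))
            return True
        return False

    def is_unfilled_template_row(self, cells: dict[str, str], values_by_var: dict[str, str]) -> bool:
        fillable = [h for h in self.spec.mandatory_headers if h not in self.spec.prefilled_headers]
        return all(not cells.get(h, "").strip() for h in fillable) and not any(values_by_var.values())

    def attach_row_data(
        self,
        row: int,
        values: dict[str, str],
        relation: Relation | None,
        harvest_lot: SeedLot | None,
        default_date: FlexDate | None,
    ) -> None:
        """Route variable-column cells to RawData on the relation or child lot."""
        for col in self.var_columns:
            value = values.get(col.header, "").strip()
            if not value:
                continue
            self.ensure_variable(col, "global", row)
            self.ensure_method(col.method)
            date = col.date or default_date
            if col.to_harvest and harvest_lot is not None:
                self.store.add_raw_data("lot", harvest_lot.name, col.variable, value, col.method, date)
            elif relation is not None:
                self.store.add_raw_data("relation", relation.relation_id, col.variable, value, col.method, date)
            else:
                self.issues.append(Issue(row, "warning", f"no attachment target for column {col.header!r}; cell ignored"))
                continue
            self.data_created += 1

    def record(self, spec: EventSpec, row: int):
        try:
            result = record_event(self.store, spec)
        except SeedTraceError as exc:
            self.issues.append(Issue(row, "error", str(exc)))
            return None
        for w in result.warnings:
            # per-column unknown-quantity warnings were already emitted above
            if "unknown quantity" not in w:
                self.issues.append(Issue(row, "warning", w))
        self.events_created += 1
        self.lots_created += len(result.children)
        return result


def import_file(store: Store, kind: str, source: str | IO[str], remap: dict[str, str] | None = None) -> ImportReport:
    """Validate and atomically apply one tabulated file.

    Raises :class:`FormatError` when the file is unreadable or lacks a
    mandatory header — distinct from a rejected (but well-formed) report.
    """
    spec = format_spec(kind)
    rows = _read_rows(source)
    if not rows or not any(cell.strip() for cell in rows[0]):
        raise FormatError("file is empty or has no header row")
    header = reverse_remap([h.strip() for h in rows[0]], remap)
    missing = [h for h in spec.mandatory_headers if h not in header]
    if missing:
        raise FormatError(f"missing mandatory header(s) for {kind}: {', '.join(missing)}")
    if len(set(header)) != len(header):
        raise FormatError("duplicate column headers")
    extra = [h for h in header if h not in spec.mandatory_headers]
    var_columns = [parse_variable_column(h) for h in extra]

    report = ImportReport(kind=kind)
    data_rows: list[tuple[int, dict[str, str]]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        cells = {h: (row[i] if i < len(row) else "") for i, h in enumerate(header)}
        data_rows.append((lineno, cells))
    report.rows_read = len(data_rows)

    snapshot = store.snapshot()
    imp = _Importer(snapshot, spec, var_columns)
    if kind == "individual_measures":
        _import_measures(imp, data_rows)
    elif kind in ("mixture", "selection"):
        _import_grouped(imp, kind, data_rows)
    else:
        _import_simple(imp, kind, data_rows)

    report.issues = sorted(imp.issues, key=lambda i: (i.row, i.severity, i.message))
    if report.errors:
        report.status = "rejected"
        return report
    report.status = "ok"
    report.events_created = imp.events_created
    report.lots_created = imp.lots_created
    report.data_points_created = imp.data_created
    snapshot.validate_integrity()
    store.restore(snapshot)
    return report


def _cell(cells: dict[str, str], name: str) -> str | None:
    v = cells.get(name, "").strip()
    return v or None


def _import_simple(imp: _Importer, kind: str, data_rows: list[tuple[int, dict[str, str]]]) -> None:
    """reproduction, cross, diffusion: one event per row, unique event_id."""
    seen_ids: set[str] = set()
    for lineno, cells in data_rows:
        values_by_var = {c.header: cells.get(c.header, "") for c in imp.var_columns}
        if imp.is_unfilled_template_row(cells, values_by_var):
            imp.issues.append(Issue(lineno, "warning", "unfilled template row; skipped"))
            continue
        event_id = _cell(cells, "event_id")
        if event_id in seen_ids:
            imp.issues.append(Issue(lineno, "error", f"duplicate event_id {event_id!r} in file"))
            continue
        if event_id:
            seen_ids.add(event_id)
        else:
            imp.issues.append(Issue(lineno, "warning", "event_id missing; a fresh id will be assigned"))
        if imp.skip_if_existing_event(event_id, lineno):
            continue
        if kind == "reproduction":
            _row_reproduction(imp, lineno, cells, event_id, values_by_var)
        elif kind == "cross":
            _row_cross(imp, lineno, cells, event_id, values_by_var)
        else:
            _row_diffusion(imp, lineno, cells, event_id, values_by_var)


def _row_reproduction(imp, lineno, cells, event_id, values_by_var) -> None:
    issues = imp.issues
    sown = _cell(cells, "sown_seed_lot")
    if sown is None:
        issues.append(Issue(lineno, "error", "missing sown_seed_lot"))
        return
    date = _parse_row_date(_cell(cells, "sowing_date"), lineno, "sowing_date", issues)
    harvest_date = _parse_row_date(_cell(cells, "harvest_date"), lineno, "harvest_date", issues, required=False)
    qty_sown, ok1 = _parse_quantity(_cell(cells, "quantity_sown_g"), lineno, "quantity_sown_g", issues)
    qty_harv, ok2 = _parse_harvest_quantity(cells, lineno, issues)
    location = imp.ensure_location(_cell(cells, "location"), lineno)
    actor = imp.ensure_person(_cell(cells, "actor"), lineno)
    if date is None or location is None or not (ok1 and ok2):
        if location is None:
            issues.append(Issue(lineno, "error", "missing location"))
        return
    spec = EventSpec(
        kind="reproduction",
        date=date,
        location=location,
        parents=[(sown, qty_sown)],
        actor=actor,
        event_id=event_id,
        harvest_date=harvest_date,
        harvested_quantity_g=qty_harv,
    )
    result = imp.record(spec, lineno)
    if result is not None:
        imp.attach_row_data(lineno, values_by_var, result.relations[0], result.children[0], harvest_date or date)


def _parse_harvest_quantity(cells, lineno, issues):
    cell = _cell(cells, "quantity_harvested_g")
    if cell is None:
        # harvest may simply not be weighed; unknown, not zero
        issues.append(Issue(lineno, "warning", "unknown quantity in column 'quantity_harvested_g'"))
        return None, True
    try:
        value = float(cell)
    except ValueError:
        issues.append(Issue(lineno, "error", f"column 'quantity_harvested_g': {cell!r} is not a number"))
        return None, False
    if value < 0:
        issues.append(Issue(lineno, "error", "column 'quantity_harvested_g': quantity must be >= 0"))
        return None, False
    return value, True


def _row_cross(imp, lineno, cells, event_id, values_by_var) -> None:
    issues = imp.issues
    mother = _cell(cells, "mother_seed_lot")
    father = _cell(cells, "father_seed_lot")
    if mother is None or father is None:
        issues.append(Issue(lineno, "error", "cross requires both mother_seed_lot and father_seed_lot"))
        return
    date = _parse_row_date(_cell(cells, "date"), lineno, "date", issues)
    location = imp.ensure_location(_cell(cells, "location"), lineno)
    actor = imp.ensure_person(_cell(cells, "actor"), lineno)
    if date is None or location is None:
        if location is None:
            issues.append(Issue(lineno, "error", "missing location"))
        return
    spec = EventSpec(
        kind="cross",
        date=date,
        location=location,
        parents=[(mother, None), (father, None)],
        mother=mother,
        father=father,
        actor=actor,
        event_id=event_id,
    )
    result = imp.record(spec, lineno)
    if result is not None:
        imp.attach_row_data(lineno, values_by_var, result.relations[0], result.children[0], date)


def _row_diffusion(imp, lineno, cells, event_id, values_by_var) -> None:
    issues = imp.issues
    parent = _cell(cells, "parent_seed_lot")
    if parent is None:
        issues.append(Issue(lineno, "error", "missing parent_seed_lot"))
        return
    date = _parse_row_date(_cell(cells, "date"), lineno, "date", issues)
    qty, ok = _parse_quantity(_cell(cells, "quantity_g"), lineno, "quantity_g", issues)
    recipient_loc = imp.ensure_location(_cell(cells, "recipient_location"), lineno)
    recipient_person = imp.ensure_person(_cell(cells, "recipient_person"), lineno)
    if recipient_loc is None:
        issues.append(Issue(lineno, "error", "missing recipient_location"))
        return
    if date is None or not ok:
        return
    if parent not in imp.store.lots:
        issues.append(Issue(lineno, "error", f"unknown parent lot {parent!r}"))
        return
    spec = EventSpec(
        kind="diffusion",
        date=date,
        location=imp.store.lots[parent].location,
        parents=[(parent, qty)],
        recipient_location=recipient_loc,
        recipient_person=recipient_person,
        event_id=event_id,
    )
    result = imp.record(spec, lineno)
    if result is not None:
        imp.attach_row_data(lineno, values_by_var, result.relations[0], result.children[0], date)


def _import_grouped(imp: _Importer, kind: str, data_rows: list[tuple[int, dict[str, str]]]) -> None:
    """mixture and selection: rows sharing an event_id form one event."""
    groups: dict[str, list[tuple[int, dict[str, str]]]] = {}
    order: list[str] = []
    for lineno, cells in data_rows:
        eid = _cell(cells, "event_id") or f"__row{lineno}"
        if eid not in groups:
            groups[eid] = []
            order.append(eid)
        groups[eid].append((lineno, cells))
    for eid in order:
        rows = groups[eid]
        first_line = rows[0][0]
        event_id = None if eid.startswith("__row") else eid
        values_by_var_all = {c.header: rows[0][1].get(c.header, "") for c in imp.var_columns}
        if len(rows) == 1 and imp.is_unfilled_template_row(rows[0][1], values_by_var_all):
            imp.issues.append(Issue(first_line, "warning", "unfilled template row; skipped"))
            continue
        if imp.skip_if_existing_event(event_id, first_line):
            continue
        # shared columns must agree across the group
        shared = ("date", "location", "actor")
        for col in shared:
            vals = {(_cell(cells, col) or "") for _, cells in rows}
            if len(vals) > 1:
                imp.issues.append(Issue(first_line, "error", f"rows of event {eid!r} disagree on column {col!r}"))
        lineno, cells = rows[0]
        date = _parse_row_date(_cell(cells, "date"), lineno, "date", imp.issues)
        location = imp.ensure_location(_cell(cells, "location"), lineno)
        actor = imp.ensure_person(_cell(cells, "actor"), lineno)
        if location is None:
            imp.issues.append(Issue(lineno, "error", "missing location"))
        if date is None or location is None:
            continue
        if kind == "mixture":
            parents = []
            ok = True
            for lineno_i, cells_i in rows:
                pname = _cell(cells_i, "parent_seed_lot")
                if pname is None:
                    imp.issues.append(Issue(lineno_i, "error", "missing parent_seed_lot"))
                    ok = False
                    continue
                qty, qok = _parse_quantity(_cell(cells_i, "quantity_used_g"), lineno_i, "quantity_used_g", imp.issues)
                ok = ok and qok
                parents.append((pname, qty))
            if not ok:
                continue
            spec = EventSpec(kind="mixture", date=date, location=location, parents=parents, actor=actor, event_id=event_id)
            result = imp.record(spec, first_line)
            if result is not None:
                for (lineno_i, cells_i), rel in zip(rows, result.relations):
                    row_vals = {c.header: cells_i.get(c.header, "") for c in imp.var_columns}
                    imp.attach_row_data(lineno_i, row_vals, rel, result.children[0], date)
        else:  # selection
            parent_names = {(_cell(cells_i, "parent_seed_lot") or "") for _, cells_i in rows}
            if len(parent_names) > 1:
                imp.issues.append(Issue(first_line, "error", f"rows of selection {eid!r} name different parent lots"))
                continue
            parent = parent_names.pop()
            if not parent:
                imp.issues.append(Issue(first_line, "error", "missing parent_seed_lot"))
                continue
            labels: list[tuple[str, float | None]] = []
            ok = True
            for lineno_i, cells_i in rows:
                label = _cell(cells_i, "selection_label")
                if label is None:
                    imp.issues.append(Issue(lineno_i, "error", "missing selection_label"))
                    ok = False
                    continue
                qty, qok = _parse_quantity(_cell(cells_i, "quantity_used_g"), lineno_i, "quantity_used_g", imp.issues)
                ok = ok and qok
                labels.append((label, qty))
            if not ok:
                continue
            spec = EventSpec(
                kind="selection",
                date=date,
                location=location,
                parents=[(parent, None)],
                selection_labels=labels,
                actor=actor,
                event_id=event_id,
            )
            result = imp.record(spec, first_line)
            if result is not None:
                for (lineno_i, cells_i), rel, child in zip(rows, result.relations, result.children):
                    row_vals = {c.header: cells_i.get(c.header, "") for c in imp.var_columns}
                    imp.attach_row_data(lineno_i, row_vals, rel, child, date)


def _import_measures(imp: _Importer, data_rows: list[tuple[int, dict[str, str]]]) -> None:
    for lineno, cells in data_rows:
        subject = _cell(cells, "subject_seed_lot")
        if subject is None:
            imp.issues.append(Issue(lineno, "error", "missing subject_seed_lot"))
            continue
        if subject not in imp.store.lots:
            imp.issues.append(Issue(lineno, "error", f"unknown seed lot {subject!r}"))
            continue
        idx_cell = _cell(cells, "individual_index")
        if idx_cell is None:
            imp.issues.append(Issue(lineno, "error", "missing individual_index"))
            continue
        try:
            index = int(idx_cell)
            if index < 1:
                raise ValueError
        except ValueError:
            imp.issues.append(Issue(lineno, "error", f"individual_index {idx_cell!r} must be a positive integer"))
            continue
        date = _parse_row_date(_cell(cells, "date"), lineno, "date", imp.issues, required=False)
        wrote = False
        for col in imp.var_columns:
            value = cells.get(col.header, "").strip()
            if not value:
                continue
            imp.ensure_variable(col, "individual", lineno)
            imp.ensure_method(col.method)
            imp.store.add_raw_data(
                "lot", subject, col.variable, value, col.method, col.date or date, individual_index=index
            )
            imp.data_created += 1
            wrote = True
        if not wrote:
            imp.issues.append(Issue(lineno, "warning", "row has no measured values"))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def _write_tsv(header: Sequence[str], rows: Iterable[Sequence[str]]) -> str:
    buf = _io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(header)
    for row in rows:
        writer.writerow(row)
    return buf.getvalue()


def export_template(
    store: Store,
    selection: Sequence[SeedLot | Relation | str],
    kind: str,
    extra_columns: Sequence[str] = (),
    remap: dict[str, str] | None = None,
) -> str:
    """Pre-filled file for the wizard workflow: one row per selected item.

    Known columns (identifier, parent lot, location) are filled; the user
    fills the remaining cells in a spreadsheet before re-submitting.
    Template event ids are deterministic (``<kind>:<lot>``), so an exported
    file that was imported once and re-submitted untouched is detected as a
    duplicate and skipped with a warning.
    """
    spec = format_spec(kind)
    if not selection:
        raise IncompatibleSelectionError("selection is empty")
    lots: list[SeedLot] = []
    for item in selection:
        if isinstance(item, str):
            lots.append(store.get_lot(item))
        elif isinstance(item, SeedLot):
            lots.append(item)
        elif isinstance(item, Relation) and kind == "individual_measures":
            lots.append(store.get_lot(item.child))
        else:
            raise IncompatibleSelectionError(
                f"{type(item).__name__} selection is incompatible with a {kind} template"
            )
    header = list(spec.mandatory_headers) + list(extra_columns)
    rows = []
    for lot in lots:
        cells = {h: "" for h in header}
        if kind == "individual_measures":
            cells["subject_seed_lot"] = lot.name
        else:
            cells["event_id"] = f"{kind}:{lot.name}"
            parent_col = "sown_seed_lot" if kind == "reproduction" else (
                "mother_seed_lot" if kind == "cross" else "parent_seed_lot"
            )
            cells[parent_col] = lot.name
            if "location" in cells:
                cells["location"] = lot.location
        rows.append([cells[h] for h in header])
    return _write_tsv(apply_remap(header, remap), rows)


def export_events(
    store: Store,
    kind: str,
    event_ids: Sequence[str] | None = None,
    data_columns: Sequence[str] = (),
    remap: dict[str, str] | None = None,
) -> str:
    """Re-emit recorded events of one kind as an import-compatible file.

    This is the "export recorded relations" half of the file workflow: the
    output re-imports into a fresh store (given the same origin lots) and
    can drive :func:`delete_from_file`.  ``data_columns`` adds variable
    columns whose cells are filled from raw data attached to each row's
    relation (or child lot for ``#harvest`` columns).
    """
    spec = format_spec(kind)
    if kind == "individual_measures":
        raise FormatError("individual_measures files are not an event export")
    ids = list(event_ids) if event_ids is not None else sorted(
        (e.event_id for e in store.events.values() if e.kind == kind),
        key=lambda eid: (store.events[eid].date.sort_key(), eid),
    )
    parsed_cols = [parse_variable_column(h) for h in data_columns]
    rows: list[list[str]] = []
    header = list(spec.mandatory_headers) + list(data_columns)
    for eid in ids:
        event = store.get_event(eid)
        if event.kind != kind:
            raise FormatError(f"event {eid!r} is a {event.kind}, not a {kind}")
        payload = event.payload_dict()
        rels = store.relations_of_event(eid)
        if kind in ("reproduction", "cross", "diffusion"):
            rel_rows = [(rels, rels[0])]
        else:
            rel_rows = [([rel], rel) for rel in rels]
        for row_rels, primary in rel_rows:
            cells = {h: "" for h in header}
            cells["event_id"] = eid
            if kind == "reproduction":
                cells["sown_seed_lot"] = primary.parent
                cells["sowing_date"] = event.date.isoformat()
                cells["location"] = event.location
                cells["actor"] = event.actor or ""
                cells["quantity_sown_g"] = _fmt_qty(primary.quantity_used_g)
                cells["harvest_date"] = payload.get("harvest_date", "")
                cells["quantity_harvested_g"] = payload.get("harvested_quantity_g", "")
            elif kind == "cross":
                cells["mother_seed_lot"] = payload.get("mother", rels[0].parent)
                cells["father_seed_lot"] = payload.get("father", rels[-1].parent)
                cells["date"] = event.date.isoformat()
                cells["location"] = event.location
                cells["actor"] = event.actor or ""
            elif kind == "diffusion":
                cells["parent_seed_lot"] = primary.parent
                cells["recipient_location"] = payload.get("recipient_location", "")
                cells["recipient_person"] = payload.get("recipient_person", "")
                cells["quantity_g"] = _fmt_qty(primary.quantity_used_g)
                cells["date"] = event.date.isoformat()
            elif kind == "mixture":
                cells["parent_seed_lot"] = primary.parent
                cells["quantity_used_g"] = _fmt_qty(primary.quantity_used_g)
                cells["date"] = event.date.isoformat()
                cells["location"] = event.location
                cells["actor"] = event.actor or ""
            else:  # selection
                labels = payload.get("labels", "").split("|")
                idx = rels.index(primary)
                cells["parent_seed_lot"] = primary.parent
                cells["selection_label"] = labels[idx] if idx < len(labels) else f"sel{idx + 1}"
                cells["date"] = event.date.isoformat()
                cells["location"] = event.location
                cells["actor"] = event.actor or ""
                cells["quantity_used_g"] = _fmt_qty(primary.quantity_used_g)
            for col in parsed_cols:
                cells[col.header] = _lookup_data(store, col, primary)
            rows.append([cells[h] for h in header])
    return _write_tsv(apply_remap(header, remap), rows)


def _fmt_qty(q: float | None) -> str:
    return "" if q is None else f"{q:g}"


def _lookup_data(store: Store, col: VariableColumn, rel: Relation) -> str:
    for rd in store.raw_data.values():
        if rd.variable != col.variable or rd.individual_index is not None:
            continue
        if col.to_harvest:
            if rd.subject_kind == "lot" and rd.subject == rel.child:
                return rd.value
        elif rd.subject_kind == "relation" and rd.subject == rel.relation_id:
            return rd.value
    return ""


def export_measure_template(store: Store, lots: Sequence[str], variables: Sequence[str], n_individuals: int = 1) -> str:
    """Individual-measures sheet skeleton: one row per (lot, individual)."""
    header = list(format_spec("individual_measures").mandatory_headers) + list(variables)
    rows = []
    for lot in lots:
        store.get_lot(lot)
        for i in range(1, n_individuals + 1):
            rows.append([lot, str(i)] + [""] * (len(header) - 2))
    return _write_tsv(header, rows)


# ---------------------------------------------------------------------------
# Delete by file
# ---------------------------------------------------------------------------


def delete_from_file(
    store: Store, source: str | IO[str], cascade: bool = False, remap: dict[str, str] | None = None
) -> DeletionReport:
    """Delete the reproduction events listed in a reproduction file.

    Every row must resolve to an existing reproduction event (by event_id);
    otherwise the whole file is rejected and nothing is deleted, mirroring
    import atomicity.
    """
    spec = format_spec("reproduction")
    rows = _read_rows(source)
    if not rows:
        raise FormatError("file is empty or has no header row")
    header = reverse_remap([h.strip() for h in rows[0]], remap)
    missing = [h for h in spec.mandatory_headers if h not in header]
    if missing:
        raise FormatError(f"missing mandatory header(s) for reproduction: {', '.join(missing)}")
    id_col = header.index("event_id")
    event_ids: list[str] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        eid = row[id_col].strip() if id_col < len(row) else ""
        if not eid:
            raise UnknownEventError(f"row {lineno}: missing event_id")
        event = store.events.get(eid)
        if event is None:
            raise UnknownEventError(f"row {lineno}: unknown event {eid!r}")
        if event.kind != "reproduction":
            raise UnknownEventError(f"row {lineno}: event {eid!r} is a {event.kind}, not a reproduction")
        event_ids.append(eid)

    snapshot = store.snapshot()
    total = DeletionReport()
    for eid in event_ids:
        if eid not in snapshot.events:
            continue  # already removed by an earlier cascade in this same file
        part = delete_event(snapshot, eid, "cascade" if cascade else "alone")
        total.events_deleted.extend(part.events_deleted)
        total.lots_deleted.extend(part.lots_deleted)
        total.data_deleted += part.data_deleted
    snapshot.validate_integrity()
    store.restore(snapshot)
    total.events_deleted.sort()
    total.lots_deleted.sort()
    return total
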