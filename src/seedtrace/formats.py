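"""Registry of the six tabulated file formats.

Five event formats (one per relation kind) plus a sixth for individual
measures.  Each has specific mandatory headers; beyond them users may add
*variable columns* holding measured values (phenotypes, environment,
cultural practices).  The header names are this package's documented
dialect — sites with their own column names remap them bijectively via
configuration, see :func:`apply_remap` / :func:`reverse_remap`.

Variable-column micro-syntax: ``name[:method][@date][#harvest]`` —
optional method, optional per-column date overriding the row's event date,
and a ``#harvest`` suffix attaching the value to the harvested/child lot
instead of the relation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dates import FlexDate, parse_date
from .errors import DateParseError, FormatError, ValidationError

FILE_KINDS: tuple[str, ...] = ("reproduction", "cross", "selection", "mixture", "diffusion", "individual_measures")


@dataclass(frozen=True)
class FileFormatSpec:
    kind: str
    mandatory_headers: tuple[str, ...]
    allows_variable_columns: bool = True
    # headers pre-filled by export_template; the rest the user fills in
    prefilled_headers: tuple[str, ...] = ()


FORMATS: dict[str, FileFormatSpec] = {
    "reproduction": FileFormatSpec(
        "reproduction",
        (
            "event_id",
            "sown_seed_lot",
            "sowing_date",
            "location",
            "actor",
            "quantity_sown_g",
            "harvest_date",
            "quantity_harvested_g",
        ),
        prefilled_headers=("event_id", "sown_seed_lot", "location"),
    ),
    "cross": FileFormatSpec(
        "cross",
        ("event_id", "mother_seed_lot", "father_seed_lot", "date", "location", "actor"),
        prefilled_headers=("event_id", "mother_seed_lot", "location"),
    ),
    "selection": FileFormatSpec(
        "selection",
        ("event_id", "parent_seed_lot", "selection_label", "date", "location", "actor", "quantity_used_g"),
        prefilled_headers=("event_id", "parent_seed_lot", "location"),
    ),
    "mixture": FileFormatSpec(
        "mixture",
        ("event_id", "parent_seed_lot", "quantity_used_g", "date", "location", "actor"),
        prefilled_headers=("event_id", "parent_seed_lot", "location"),
    ),
    "diffusion": FileFormatSpec(
        "diffusion",
        ("event_id", "parent_seed_lot", "recipient_location", "recipient_person", "quantity_g", "date"),
        prefilled_headers=("event_id", "parent_seed_lot"),
    ),
    "individual_measures": FileFormatSpec(
        "individual_measures",
        ("subject_seed_lot", "individual_index", "date"),
        prefilled_headers=("subject_seed_lot",),
    ),
}


def format_spec(kind: str) -> FileFormatSpec:
    try:
        return FORMATS[kind]
    except KeyError:
        raise FormatError(f"unknown file kind {kind!r}; expected one of {FILE_KINDS}") from None


@dataclass(frozen=True)
class VariableColumn:
    """A parsed variable-column header."""

    header: str
    variable: str
    method: str | None
    date: FlexDate | None
    to_harvest: bool  # attach to the harvested/child lot instead of the relation


def parse_variable_column(header: str) -> VariableColumn:
    text = header.strip()
    to_harvest = text.endswith("#harvest")
    if to_harvest:
        text = text[: -len("#harvest")]
    date: FlexDate | None = None
    if "@" in text:
        text, _, date_text = text.rpartition("@")
        try:
            date = parse_date(date_text)
        except DateParseError as exc:
            raise FormatError(f"bad date in variable column {header!r}: {exc}") from exc
    method: str | None = None
    if ":" in text:
        text, _, method = text.partition(":")
        method = method.strip() or None
    name = text.strip()
    if not name:
        raise FormatError(f"variable column {header!r} has an empty variable name")
    return VariableColumn(header=header, variable=name, method=method, date=date, to_harvest=to_harvest)


def validate_remap(remap: dict[str, str]) -> None:
    """A site header remapping must be bijective on the names it covers."""
    values = list(remap.values())
    if len(set(values)) != len(values):
        raise ValidationError("header remapping must be bijective (duplicate site names)")


def apply_remap(headers: list[str], remap: dict[str, str] | None) -> list[str]:
    """canonical -> site names, for writing."""
    if not remap:
        return list(headers)
    validate_remap(remap)
    return [remap.get(h, h) for h in headers]


def reverse_remap(headers: list[str], remap: dict[str, str] | None) -> list[str]:
    """site -> canonical names, for reading."""
    if not remap:
        return list(headers)
    validate_remap(remap)
    inverse = {v: k for k, v in remap.items()}
    return [inverse.get(h, h) for h in headers]
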