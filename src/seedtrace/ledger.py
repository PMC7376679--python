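"""Gram-based stock accounting per seed lot.

The balance of a lot is replayed from three entry kinds: the *initial*
credit (the lot's starting grams, absent when unknown), a *debit* for every
relation in which the lot is a parent with a known quantity, and
*inventory* resets — dated absolute measurements that override whatever the
replay computed before them.  Entries at the same date order
initial < debit < inventory: an inventory taken the day of a sowing
reflects post-sowing reality.  Negative balances are kept visible (never
clamped) and flagged, because they reveal data-entry errors.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dates import FlexDate
from .model import Store, round_grams

_KIND_RANK = {"initial": 0, "debit": 1, "inventory": 2}

WARN_NEGATIVE = "negative balance"
WARN_UNKNOWN_INITIAL = "initial quantity unknown; balance replayed from 0"
WARN_APPROXIMATE = "stock approximate: relation(s) with unknown quantity"


@dataclass(frozen=True)
class LedgerEntry:
    date: FlexDate
    kind: str  # initial | debit | inventory
    amount_g: float  # debit: grams removed; inventory: absolute measurement; initial: starting grams
    balance_after_g: float
    source: str  # human-readable provenance (relation/event id, inventory id, or the lot itself)


def _raw_entries(store: Store, lot: str) -> list[tuple[FlexDate, int, int, str, float, str]]:
    """(date, kind_rank, source_id, kind, amount, source) tuples, unsorted."""
    entries = []
    for rel_id in store.children_index().get(lot, ()):
        rel = store.relations[rel_id]
        if rel.quantity_used_g is None:
            continue
        ev = store.events[rel.event_id]
        entries.append((ev.date, _KIND_RANK["debit"], rel_id, "debit", rel.quantity_used_g, f"relation {rel_id} ({ev.kind} {ev.event_id})"))
    for uid, upd in store.inventory.items():
        if upd.lot == lot:
            entries.append((upd.date, _KIND_RANK["inventory"], uid, "inventory", upd.measured_quantity_g, f"inventory {uid}"))
    return entries


def stock_history(store: Store, lot: str) -> tuple[list[LedgerEntry], list[str]]:
    """Replay the full dated stock history of ``lot``.

    Returns the ordered entries and accumulated warnings.  Ordering depends
    only on (date, kind, source id), never on insertion order, so replay is
    deterministic.  The initial entry, when the initial quantity is known,
    always comes first.
    """
    record = store.get_lot(lot)
    warnings: list[str] = []
    others = sorted(_raw_entries(store, lot), key=lambda t: (t[0].sort_key(), t[1], t[2]))

    entries: list[LedgerEntry] = []
    if record.initial_quantity_g is not None:
        balance = record.initial_quantity_g
        entries.append(
            LedgerEntry(FlexDate(record.creation_year), "initial", record.initial_quantity_g, balance, f"seed lot {lot}")
        )
    else:
        balance = 0.0
        if others:
            warnings.append(WARN_UNKNOWN_INITIAL)

    for date, _, _, kind, amount, source in others:
        if kind == "debit":
            balance = round_grams(balance - amount)
        else:  # inventory reset: absolute measurement dominates history before it
            balance = amount
        entries.append(LedgerEntry(date, kind, amount, balance, source))

    if any(
        rel.quantity_used_g is None
        for rid in store.children_index().get(lot, ())
        for rel in [store.relations[rid]]
    ):
        warnings.append(WARN_APPROXIMATE)
    if any(e.balance_after_g < 0 for e in entries):
        warnings.append(WARN_NEGATIVE)
    return entries, warnings


def current_stock(store: Store, lot: str, as_of: FlexDate | None = None) -> tuple[float | None, list[str]]:
    """Balance after the last ledger entry at or before ``as_of``.

    ``None`` means the stock is unknown (no entries, or ``as_of`` predates
    the first entry) — deliberately distinct from 0 g.
    """
    entries, warnings = stock_history(store, lot)
    if as_of is not None:
        entries = [e for e in entries if e.date.sort_key() <= as_of.sort_key()]
    if not entries:
        return None, warnings
    return entries[-1].balance_after_g, warnings


def history_tsv(store: Store, lot: str) -> str:
    """Stock history as TSV (date, kind, amount_g, balance_after_g, source)."""
    entries, _ = stock_history(store, lot)
    lines = ["date\tkind\tamount_g\tbalance_after_g\tsource"]
    for e in entries:
        lines.append(f"{e.date.isoformat()}\t{e.kind}\t{e.amount_g:g}\t{e.balance_after_g:g}\t{e.source}")
    return "\n".join(lines) + "\n"
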