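"""Pedigree traversal, generation counting and event deletion.

Generation semantics
--------------------
The generation number of a lot counts **reproduction** events along its
ancestry.  A cross or a mixture creates a new genetic entity, so it resets
the count to zero; selection and diffusion are transparent (they neither
count nor reset).  With several ancestry paths the total is the maximum
over paths.  The *local* generation is the length of the maximal trailing
run of reproduction events whose event location equals the lot's own
location — a diffusion (or any non-reproduction event, or a reproduction
elsewhere) breaks the run.  The quality flag is ``minimum`` when any
ancestry path ends at a lot that is not marked as an origin yet has no
recorded parents: the history is truncated and the true generation can
only be larger.  These semantics are this package's resolution of an
informally specified notion; they are isolated behind
:class:`GenerationInfo` so an alternate rule is swappable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import DownstreamExistsError
from .model import Relation, SeedLot, Store


@dataclass(frozen=True)
class GenerationInfo:
    """total/local reproduction-generation counts with a quality flag."""

    total: int
    local: int
    quality: str  # "exact" | "minimum"


@dataclass
class DeletionReport:
    events_deleted: list[str] = field(default_factory=list)
    lots_deleted: list[str] = field(default_factory=list)
    data_deleted: int = 0

    def summary(self) -> str:
        lines = [
            f"events deleted: {len(self.events_deleted)}",
            f"seed lots deleted: {len(self.lots_deleted)}",
            f"data points deleted: {self.data_deleted}",
        ]
        for eid in self.events_deleted:
            lines.append(f"  event\t{eid}")
        for name in self.lots_deleted:
            lines.append(f"  lot\t{name}")
        return "\n".join(lines)


def _event_sort_key(store: Store, rel: Relation):
    return (store.events[rel.event_id].date.sort_key(), rel.relation_id)


def parents(store: Store, lot: str) -> list[tuple[SeedLot, Relation]]:
    """Parent lots of ``lot`` with their relations, ordered by event date."""
    store.get_lot(lot)
    rels = [store.relations[i] for i in store.parents_index().get(lot, [])]
    rels.sort(key=lambda r: _event_sort_key(store, r))
    return [(store.lots[r.parent], r) for r in rels]


def children(store: Store, lot: str) -> list[tuple[SeedLot, Relation]]:
    store.get_lot(lot)
    rels = [store.relations[i] for i in store.children_index().get(lot, [])]
    rels.sort(key=lambda r: _event_sort_key(store, r))
    return [(store.lots[r.child], r) for r in rels]


def ancestors(store: Store, lot: str, max_depth: int | None = None) -> set[str]:
    """Names of all proper ancestors of ``lot`` (BFS up the relation graph)."""
    return _reach(store, lot, store.parents_index(), "parent", max_depth)


def descendants(store: Store, lot: str, max_depth: int | None = None) -> set[str]:
    return _reach(store, lot, store.children_index(), "child", max_depth)


def _reach(store: Store, lot: str, index: dict[str, list[int]], attr: str, max_depth: int | None) -> set[str]:
    store.get_lot(lot)
    seen: set[str] = set()
    frontier = [lot]
    depth = 0
    while frontier and (max_depth is None or depth < max_depth):
        depth += 1
        nxt: list[str] = []
        for name in frontier:
            for rel_id in index.get(name, ()):
                other = getattr(store.relations[rel_id], attr)
                if other not in seen:
                    seen.add(other)
                    nxt.append(other)
        frontier = nxt
    return seen


def lineage_subgraph(store: Store, lot: str, direction: str = "ancestors", max_depth: int | None = None) -> nx.DiGraph:
    """The ancestor (or descendant) subgraph of ``lot``, self included."""
    reach = ancestors(store, lot, max_depth) if direction == "ancestors" else descendants(store, lot, max_depth)
    nodes = reach | {lot}
    g = store.to_networkx()
    return g.subgraph(nodes).copy()


def generation(store: Store, lot: str) -> GenerationInfo:
    """Generation counts for ``lot``; see the module docstring for semantics."""
    store.get_lot(lot)
    parent_idx = store.parents_index()

    total_memo: dict[str, int] = {}
    exact_memo: dict[str, bool] = {}

    def total_of(name: str) -> int:
        if name in total_memo:
            return total_memo[name]
        total_memo[name] = 0  # placeholder; graph is a DAG so no true recursion on it
        best = 0
        for rel_id in parent_idx.get(name, ()):
            rel = store.relations[rel_id]
            kind = store.events[rel.event_id].kind
            if kind in ("cross", "mixture"):
                cand = 0
            elif kind == "reproduction":
                cand = total_of(rel.parent) + 1
            else:  # selection, diffusion: transparent
                cand = total_of(rel.parent)
            best = max(best, cand)
        total_memo[name] = best
        return best

    def exact_of(name: str) -> bool:
        if name in exact_memo:
            return exact_memo[name]
        rels = parent_idx.get(name, ())
        if not rels:
            ok = store.lots[name].origin_flag
        else:
            ok = all(exact_of(store.relations[r].parent) for r in rels)
        exact_memo[name] = ok
        return ok

    loc = store.lots[lot].location
    local_memo: dict[str, int] = {}

    def local_of(name: str) -> int:
        if name in local_memo:
            return local_memo[name]
        local_memo[name] = 0
        best = 0
        for rel_id in parent_idx.get(name, ()):
            rel = store.relations[rel_id]
            if store.events[rel.event_id].kind == "reproduction" and store.events[rel.event_id].location == loc:
                best = max(best, local_of(rel.parent) + 1)
        local_memo[name] = best
        return best

    total = total_of(lot)
    local = min(local_of(lot), total)
    quality = "exact" if exact_of(lot) else "minimum"
    return GenerationInfo(total=total, local=local, quality=quality)


def delete_event(store: Store, event_id: str, mode: str = "alone") -> DeletionReport:
    """Delete an event alone or in cascade.

    ``cascade`` removes the event, its relations and child lots, every
    downstream event reachable through those lots, and all raw data attached
    to any deleted object.  ``alone`` requires that no downstream event uses
    any child lot of this event.  The store stays referentially intact.
    """
    if mode not in ("alone", "cascade"):
        raise ValueError("mode must be 'alone' or 'cascade'")
    store.get_event(event_id)

    children_idx = store.children_index()

    def child_lots_of(eid: str) -> set[str]:
        return {r.child for r in store.relations_of_event(eid)}

    doomed_events: list[str] = []
    doomed_lots: set[str] = set()
    queue = [event_id]
    seen_events = {event_id}
    while queue:
        eid = queue.pop(0)
        doomed_events.append(eid)
        for lot in sorted(child_lots_of(eid)):
            doomed_lots.add(lot)
            downstream = {store.relations[r].event_id for r in children_idx.get(lot, ())}
            if mode == "alone" and downstream:
                raise DownstreamExistsError(
                    f"event {event_id!r} has downstream events using lot {lot!r}; use cascade"
                )
            for down in sorted(downstream):
                if down not in seen_events:
                    seen_events.add(down)
                    queue.append(down)

    doomed_rel_ids = {rid for rid, r in store.relations.items() if r.event_id in seen_events}
    data_deleted = 0
    for did in [d for d in list(store.raw_data)]:
        rd = store.raw_data[did]
        if (rd.subject_kind == "lot" and rd.subject in doomed_lots) or (
            rd.subject_kind == "relation" and rd.subject in doomed_rel_ids
        ):
            del store.raw_data[did]
            data_deleted += 1
    for uid in [u for u, upd in list(store.inventory.items()) if upd.lot in doomed_lots]:
        del store.inventory[uid]
    for rid in doomed_rel_ids:
        del store.relations[rid]
    for lot in doomed_lots:
        del store.lots[lot]
    for eid in seen_events:
        del store.events[eid]
    return DeletionReport(events_deleted=sorted(doomed_events), lots_deleted=sorted(doomed_lots), data_deleted=data_deleted)
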