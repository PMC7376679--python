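import pytest

import seedtrace as st


@pytest.fixture
def store():
    """Empty store with two farms, two farmers and one wheat population."""
    s = st.Store()
    s.register(st.Location("Farm-A"))
    s.register(st.Location("Farm-B"))
    s.register(st.Person("Alice", role="farmer", location="Farm-A"))
    s.register(st.Person("Bob", role="farmer", location="Farm-B"))
    s.register(st.Germplasm("Renan", "Triticum aestivum"))
    return s


@pytest.fixture
def renan_lot(store):
    return store.create_seed_lot("Renan", "Farm-A", 2015, 1000)


def make_reproduction(store, parent, location, sow_year, sown_g=150, harvested_g=2000, actor=None):
    spec = st.EventSpec(
        kind="reproduction",
        date=st.FlexDate(sow_year, 10, 20),
        location=location,
        parents=[(parent, sown_g)],
        actor=actor,
        harvest_date=st.FlexDate(sow_year + 1, 7, 15),
        harvested_quantity_g=harvested_g,
    )
    return st.record_event(store, spec)


@pytest.fixture
def repro_chain(store, renan_lot):
    """origin -> repro(Farm-A) -> repro(Farm-A) -> diffusion to Farm-B -> repro(Farm-B)."""
    r1 = make_reproduction(store, renan_lot.name, "Farm-A", 2015)
    r2 = make_reproduction(store, r1.children[0].name, "Farm-A", 2016, harvested_g=1800)
    d = st.record_diffusion(store, r2.children[0].name, "Farm-B", "Bob", 200, st.FlexDate(2017, 8, 20))
    r3 = make_reproduction(store, d.children[0].name, "Farm-B", 2017, harvested_g=1500)
    return {"origin": renan_lot, "r1": r1, "r2": r2, "d": d, "r3": r3}


def make_cross_store():
    """Origin lots A, B, D, E at one station, ready for cross compositions."""
    s = st.Store()
    s.register(st.Location("Station"))
    for name in "ABDE":
        s.register(st.Germplasm(name, "Triticum aestivum"))
        s.create_seed_lot(name, "Station", 2015, 500, name=f"{name}-lot")
    return s


@pytest.fixture
def cross_store():
    return make_cross_store()


@pytest.fixture
def backcross():
    """AxB -> C, then CxB: the two-step backcross composition."""
    s = make_cross_store()
    c = st.record_event(
        s,
        st.EventSpec(
            "cross", st.FlexDate(2016, 6, 1), "Station", parents=[("A-lot", None), ("B-lot", None)], child_name="C-lot"
        ),
    )
    bc = st.record_event(
        s,
        st.EventSpec(
            "cross", st.FlexDate(2017, 6, 1), "Station", parents=[("C-lot", None), ("B-lot", None)], child_name="BC-lot"
        ),
    )
    return {"store": s, "c": c, "bc": bc}


@pytest.fixture
def polycross():
    """AxB -> C, DxE -> F, then FxC."""
    s = make_cross_store()
    c = st.record_event(
        s,
        st.EventSpec(
            "cross", st.FlexDate(2016, 6, 1), "Station", parents=[("A-lot", None), ("B-lot", None)], child_name="C-lot"
        ),
    )
    f = st.record_event(
        s,
        st.EventSpec(
            "cross", st.FlexDate(2016, 6, 2), "Station", parents=[("D-lot", None), ("E-lot", None)], child_name="F-lot"
        ),
    )
    pc = st.record_event(
        s,
        st.EventSpec(
            "cross", st.FlexDate(2017, 6, 1), "Station", parents=[("F-lot", None), ("C-lot", None)], child_name="PC-lot"
        ),
    )
    return {"store": s, "c": c, "f": f, "pc": pc}


# ---------------------------------------------------------------------------
# independent oracles (used by several test modules)
# ---------------------------------------------------------------------------


def reachable_ancestors(store, lot):
    """Brute-force reachability over the raw relation table (no lineage code)."""
    edges = {}
    for rel in store.relations.values():
        edges.setdefault(rel.child, set()).add(rel.parent)
    seen, stack = set(), [lot]
    while stack:
        for parent in edges.get(stack.pop(), ()):
            if parent not in seen:
                seen.add(parent)
                stack.append(parent)
    return seen


def enumerate_generation(store, lot):
    """Exhaustive path enumeration oracle for generation counts.

    Walks every ancestry path; per path, total counts reproduction events
    after the last cross/mixture, the local run counts trailing
    reproductions at the lot's location, and quality is minimum when the
    path's end lot is parentless without the origin flag.
    """
    parent_rels = {}
    for rel in store.relations.values():
        parent_rels.setdefault(rel.child, []).append(rel)
    loc = store.lots[lot].location

    totals, locals_, exact = [], [], []

    def walk(name, path):
        rels = parent_rels.get(name, [])
        if not rels:
            kinds = [store.events[r.event_id].kind for r in path]  # lot-side first
            total = 0
            for kind in kinds:
                if kind in ("cross", "mixture"):
                    break
                if kind == "reproduction":
                    total += 1
            run = 0
            for r in path:
                ev = store.events[r.event_id]
                if ev.kind == "reproduction" and ev.location == loc:
                    run += 1
                else:
                    break
            totals.append(total)
            locals_.append(run)
            exact.append(store.lots[name].origin_flag)
            return
        for r in rels:
            walk(r.parent, path + [r])

    walk(lot, [])
    return {
        "total": max(totals),
        "local": min(max(locals_), max(totals)),
        "quality": "exact" if all(exact) else "minimum",
    }
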