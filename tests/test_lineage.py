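"""Pedigree traversal, generation counting and event deletion."""

import networkx as nx
import pytest

import seedtrace as st
from conftest import enumerate_generation, make_reproduction, reachable_ancestors


class TestAdjacency:
    def test_origin_lot_has_no_parents(self, store, renan_lot):
        assert st.parents(store, renan_lot.name) == []

    def test_unknown_lot_raises(self, store):
        with pytest.raises(st.UnknownLotError):
            st.parents(store, "ghost")
        with pytest.raises(st.UnknownLotError):
            st.ancestors(store, "ghost")

    def test_children_of_parents_contains_lot(self, store, repro_chain):
        for lot in store.lots:
            for parent, _ in st.parents(store, lot):
                assert lot in {c.name for c, _ in st.children(store, parent.name)}

    def test_parents_ordered_by_event_date(self, store, renan_lot):
        late = make_reproduction(store, renan_lot.name, "Farm-A", 2017)
        early = make_reproduction(store, renan_lot.name, "Farm-A", 2015)
        kids = [c.name for c, _ in st.children(store, renan_lot.name)]
        assert kids == [early.children[0].name, late.children[0].name]


class TestReachability:
    def test_polycross_ancestor_set(self, polycross):
        s = polycross["store"]
        assert st.ancestors(s, "PC-lot") == reachable_ancestors(s, "PC-lot") == {
            "A-lot",
            "B-lot",
            "C-lot",
            "D-lot",
            "E-lot",
            "F-lot",
        }

    def test_max_depth_one_equals_parents(self, polycross):
        s = polycross["store"]
        assert st.ancestors(s, "PC-lot", max_depth=1) == {p.name for p, _ in st.parents(s, "PC-lot")}

    def test_descendants_of_unused_lot_empty(self, store, renan_lot):
        assert st.descendants(store, renan_lot.name) == set()

    def test_descendants_mirror_ancestors(self, store, repro_chain):
        tip = repro_chain["r3"].children[0].name
        origin = repro_chain["origin"].name
        assert origin in st.ancestors(store, tip)
        assert tip in st.descendants(store, origin)

    def test_subgraph_closed_under_traversal(self, polycross):
        g = st.lineage_subgraph(polycross["store"], "PC-lot")
        assert set(g.nodes) == {"A-lot", "B-lot", "C-lot", "D-lot", "E-lot", "F-lot", "PC-lot"}
        assert nx.is_directed_acyclic_graph(g)


class TestGeneration:
    def test_origin_lot_is_generation_zero(self, store, renan_lot):
        assert st.generation(store, renan_lot.name) == st.GenerationInfo(0, 0, "exact")

    def test_chain_with_diffusion(self, store, repro_chain):
        # origin -> repro(A) -> repro(A) -> diffusion to B -> repro(B)
        tip = repro_chain["r3"].children[0].name
        assert st.generation(store, tip) == st.GenerationInfo(total=3, local=1, quality="exact")

    def test_truncated_history_flags_minimum(self, store, repro_chain):
        origin = repro_chain["origin"]
        store.lots[origin.name] = st.SeedLot(
            origin.name, origin.germplasm_key, origin.location, origin.creation_year,
            origin.initial_quantity_g, origin_flag=False,
        )
        tip = repro_chain["r3"].children[0].name
        info = st.generation(store, tip)
        assert info.quality == "minimum"
        assert info.total == 3

    def test_cross_resets_count(self, backcross):
        s = backcross["store"]
        res = make_reproduction(s, "BC-lot", "Station", 2018)
        info = st.generation(s, res.children[0].name)
        assert info.total == 1  # one reproduction since the backcross
        assert info.local == 1

    def test_matches_path_enumeration_oracle(self, store, repro_chain, polycross):
        for s in (store, polycross["store"]):
            for lot in s.lots:
                got = st.generation(s, lot)
                want = enumerate_generation(s, lot)
                assert (got.total, got.local, got.quality) == (
                    want["total"],
                    want["local"],
                    want["quality"],
                ), lot

    def test_local_never_exceeds_total(self, store, repro_chain):
        for lot in store.lots:
            info = st.generation(store, lot)
            assert info.local <= info.total


class TestDeletion:
    @pytest.fixture
    def chain3(self, store, renan_lot):
        """origin -> repro -> repro -> repro (3 events, 3 harvested lots)."""
        r1 = make_reproduction(store, renan_lot.name, "Farm-A", 2015)
        r2 = make_reproduction(store, r1.children[0].name, "Farm-A", 2016)
        r3 = make_reproduction(store, r2.children[0].name, "Farm-A", 2017)
        return [r1, r2, r3]

    def test_cascade_deletes_whole_subtree(self, store, chain3):
        report = st.delete_event(store, chain3[0].event.event_id, "cascade")
        assert len(report.events_deleted) == 3
        assert len(report.lots_deleted) == 3
        assert len(store.events) == 0
        store.validate_integrity()

    def test_alone_on_leaf(self, store, chain3):
        report = st.delete_event(store, chain3[2].event.event_id, "alone")
        assert report.events_deleted == [chain3[2].event.event_id]
        assert len(store.events) == 2
        store.validate_integrity()

    def test_alone_on_non_leaf_rejected(self, store, chain3):
        with pytest.raises(st.DownstreamExistsError):
            st.delete_event(store, chain3[0].event.event_id, "alone")

    def test_repeat_delete_raises_unknown(self, store, chain3):
        st.delete_event(store, chain3[0].event.event_id, "cascade")
        with pytest.raises(st.UnknownEventError):
            st.delete_event(store, chain3[0].event.event_id, "cascade")

    def test_cascade_removes_attached_data(self, store, chain3):
        store.register(st.Variable("tkw"))
        rel = chain3[1].relations[0]
        store.add_raw_data("relation", rel.relation_id, "tkw", "44.0")
        store.add_raw_data("lot", chain3[2].children[0].name, "tkw", "45.5")
        store.add_inventory(chain3[1].children[0].name, st.FlexDate(2017, 1, 1), 500)
        report = st.delete_event(store, chain3[1].event.event_id, "cascade")
        assert report.data_deleted == 2
        assert store.raw_data == {}
        assert store.inventory == {}
        store.validate_integrity()

    def test_cascade_keeps_unrelated_branches(self, store, chain3, renan_lot):
        side = make_reproduction(store, renan_lot.name, "Farm-B", 2016)
        st.delete_event(store, chain3[0].event.event_id, "cascade")
        assert side.event.event_id in store.events
        assert side.children[0].name in store.lots
        store.validate_integrity()

    def test_mixture_event_survives_partial_parent_deletion(self, store, chain3, renan_lot):
        # a mixture drawing from a doomed branch and a safe branch is itself doomed,
        # but its safe parent lot must survive
        safe = make_reproduction(store, renan_lot.name, "Farm-B", 2016)
        mix = st.record_event(
            store,
            st.EventSpec(
                "mixture",
                st.FlexDate(2018, 9, 1),
                "Farm-A",
                parents=[(chain3[2].children[0].name, 100), (safe.children[0].name, 100)],
            ),
        )
        report = st.delete_event(store, chain3[0].event.event_id, "cascade")
        assert mix.event.event_id in report.events_deleted
        assert safe.children[0].name in store.lots
        store.validate_integrity()
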