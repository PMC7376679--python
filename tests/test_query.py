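"""Query API: three-table routing, filters, cards, search."""

import pytest

import seedtrace as st
from conftest import make_reproduction


@pytest.fixture
def data_store(store, repro_chain):
    """2 lot-level + 3 relation-level global measures + 4 individual measures."""
    store.register(st.Variable("tkw", scope="phenotype", level="global"))
    store.register(st.Variable("soil_type", scope="environment", level="global"))
    store.register(st.Variable("plant_height", scope="phenotype", level="individual"))
    r1, r3 = repro_chain["r1"], repro_chain["r3"]
    harvest1 = r1.children[0].name
    harvest3 = r3.children[0].name
    # lot-attached
    store.add_raw_data("lot", harvest1, "tkw", "43.1", date=st.FlexDate(2016, 8, 1))
    store.add_raw_data("lot", harvest3, "soil_type", "clay")
    # relation-attached (global)
    store.add_raw_data("relation", r1.relations[0].relation_id, "tkw", "41.0", date=st.FlexDate(2016, 8, 2))
    store.add_raw_data("relation", r3.relations[0].relation_id, "tkw", "44.5", date=st.FlexDate(2018, 8, 2))
    store.add_raw_data("relation", r3.relations[0].relation_id, "soil_type", "loam")
    # individual
    for i, h in enumerate((88.0, 92.5, 101.0, 79.5), start=1):
        store.add_raw_data("lot", harvest3, "plant_height", str(h), date=st.FlexDate(2018, 6, 15), individual_index=i)
    return store


class TestQueryData:
    def test_empty_store_three_empty_tables(self):
        result = st.query_data(st.Store())
        assert [len(t) for t in result.tables()] == [0, 0, 0]

    def test_unfiltered_row_counts(self, data_store):
        result = st.query_data(data_store)
        assert [len(t) for t in result.tables()] == [2, 3, 4]

    def test_filter_by_variable(self, data_store):
        result = st.query_data(data_store, st.QueryFilter(variable="tkw"))
        assert [len(t) for t in result.tables()] == [1, 2, 0]

    def test_filter_by_location_and_actor(self, data_store):
        by_loc = st.query_data(data_store, st.QueryFilter(location="Farm-B"))
        assert [len(t) for t in by_loc.tables()] == [1, 2, 4]

    def test_date_range_uses_measure_date_with_event_fallback(self, data_store):
        in_2016 = st.query_data(
            data_store, st.QueryFilter(date_range=(st.FlexDate(2016, 1, 1), st.FlexDate(2016, 12, 31)))
        )
        assert [len(t) for t in in_2016.tables()] == [1, 1, 0]
        nothing = st.query_data(
            data_store, st.QueryFilter(date_range=(st.FlexDate(1901, 1, 1), st.FlexDate(1901, 12, 31)))
        )
        assert [len(t) for t in nothing.tables()] == [0, 0, 0]

    def test_stronger_filter_is_row_subset(self, data_store):
        loose = st.query_data(data_store, st.QueryFilter(variable="tkw"))
        tight = st.query_data(data_store, st.QueryFilter(variable="tkw", location="Farm-B"))
        for lt, tt in zip(loose.tables(), tight.tables()):
            assert set(tt.rows) <= set(lt.rows)

    def test_tables_export_as_tsv(self, data_store):
        result = st.query_data(data_store)
        text = result.relation_table.to_tsv()
        assert text.startswith("subject\tvariable\tmethod\tdate\tvalue\tlevel\tindividual_index\n")
        assert len(text.strip().split("\n")) == 4


class TestCards:
    def test_seed_lot_card_has_four_sections(self, data_store, repro_chain):
        card = st.seed_lot_card(data_store, repro_chain["r3"].children[0].name)
        assert len(card.sections()) == 4
        assert card.identity["species"] == "Triticum aestivum"
        assert card.identity["location"] == "Farm-B"

    def test_origin_lot_card(self, store, renan_lot):
        card = st.seed_lot_card(store, renan_lot.name)
        assert card.history["created_by"] == []
        current, entries, _ = card.stock
        assert current == 1000 and [e.kind for e in entries] == ["initial"]
        assert "no creating event" in card.to_tsv()["history"]

    def test_card_history_lists_creator_and_uses(self, backcross):
        s = backcross["store"]
        card = st.seed_lot_card(s, "C-lot")
        assert len(card.history["created_by"]) == 2  # two parents, one cross event
        assert all("cross" in line for line in card.history["created_by"])
        assert len(card.history["used_in"]) == 1  # the backcross

    def test_card_stock_matches_ledger(self, data_store):
        for lot in data_store.lots:
            card = st.seed_lot_card(data_store, lot)
            assert card.stock[0] == st.current_stock(data_store, lot)[0]

    def test_card_sections_export_tsv(self, data_store, repro_chain):
        sections = st.seed_lot_card(data_store, repro_chain["r3"].children[0].name).to_tsv()
        assert set(sections) == {"identity", "history", "data", "stock"}
        assert all(isinstance(v, str) and v for v in sections.values())

    def test_relation_card_two_sections(self, data_store, repro_chain):
        r3 = repro_chain["r3"]
        card = st.relation_card(data_store, r3.relations[0].parent, r3.children[0].name)
        assert len(card.sections()) == 2
        assert len(card.info) == 1
        # the card shows data for the relation and its child lot: tkw + soil_type
        # on the relation, soil_type on the harvested lot
        assert len(card.data["global"]) == 3
        assert len(card.data["individual"]) == 4

    def test_relation_card_repeated_pairs_newest_first(self, store, renan_lot):
        a = make_reproduction(store, renan_lot.name, "Farm-A", 2015)
        store.lots.pop(a.children[0].name)  # free the name so the same pair repeats
        lot = store.create_seed_lot("Renan", "Farm-A", 2016, name=a.children[0].name, origin=False)
        b_rel = store.add_relation(renan_lot.name, lot.name, a.event.event_id, 99)
        card = st.relation_card(store, renan_lot.name, lot.name)
        assert len(card.info) == 2

    def test_unknown_relation_raises(self, store, renan_lot):
        other = store.create_seed_lot("Renan", "Farm-B", 2015)
        with pytest.raises(st.UnknownRelationError):
            st.relation_card(store, renan_lot.name, other.name)


class TestSearch:
    def test_prefix_finds_lots_and_germplasm(self, store, repro_chain):
        hits = st.search(store, "Ren")
        names = {h.name for h in hits}
        assert "Renan" in names
        assert all(n in names for n in store.lots)

    def test_exact_match_ranks_first(self, store, repro_chain):
        hits = st.search(store, "renan")
        assert hits[0].name == "Renan" and hits[0].rank == 0

    def test_no_match_is_empty(self, store, repro_chain):
        assert st.search(store, "zzz") == []

    def test_extension_shrinks_results(self, store, repro_chain):
        base = {(h.kind, h.name) for h in st.search(store, "Renan_Farm")}
        extended = {(h.kind, h.name) for h in st.search(store, "Renan_Farm-B")}
        assert extended <= base

    def test_substring_ranks_after_prefix(self, store, repro_chain):
        hits = st.search(store, "Farm-B")
        assert hits  # matched inside lot names and relation labels
        assert all(h.rank == 2 for h in hits if h.kind == "seed_lot")
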