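"""Registry semantics: natural keys, idempotency, invariants, persistence."""

import pytest

import seedtrace as st


class TestRegistration:
    def test_idempotent_reregistration(self, store):
        key1 = store.register(st.Location("Farm-A"))
        key2 = store.register(st.Location("Farm-A"))
        assert key1 == key2 == "Farm-A"

    def test_same_key_different_payload_rejected(self, store):
        with pytest.raises(st.DuplicateKeyError):
            store.register(st.Location("Farm-A", kind="institute"))

    def test_germplasm_resolvable_by_name_and_species(self, store):
        g = store.resolve_germplasm("Renan", "Triticum aestivum")
        assert g.key == ("Renan", "Triticum aestivum")

    def test_germplasm_identity_is_name_species_pair(self, store):
        store.register(st.Germplasm("Renan", "wheat"))
        store.register(st.Germplasm("Renan", "bread wheat"))
        keys = {g.key for g in store.germplasms.values() if g.name == "Renan"}
        assert ("Renan", "wheat") in keys and ("Renan", "bread wheat") in keys
        assert len(keys) == 3  # incl. the fixture's Triticum aestivum
        with pytest.raises(st.ValidationError, match="ambiguous"):
            store.resolve_germplasm("Renan")

    def test_invalid_entities_rejected(self):
        with pytest.raises(st.ValidationError):
            st.Germplasm("Renan", "")
        with pytest.raises(st.ValidationError):
            st.Location("X", kind="spaceship")
        with pytest.raises(st.ValidationError):
            st.Variable("height", level="per-plant")


class TestSeedLots:
    def test_default_name_follows_pattern(self, store, renan_lot):
        assert renan_lot.name == "Renan_Farm-A_2015"
        assert renan_lot.origin_flag is True

    def test_negative_initial_quantity_rejected(self, store):
        with pytest.raises(st.ValidationError):
            store.create_seed_lot("Renan", "Farm-A", 2015, -5)

    def test_second_direct_creation_gets_suffix(self, store, renan_lot):
        second = store.create_seed_lot("Renan", "Farm-A", 2015, 500)
        assert second.name == "Renan_Farm-A_2015_2"

    def test_duplicate_explicit_name_rejected(self, store, renan_lot):
        with pytest.raises(st.DuplicateNameError):
            store.create_seed_lot("Renan", "Farm-A", 2016, name=renan_lot.name)

    def test_unknown_quantity_is_not_zero(self, store):
        lot = store.create_seed_lot("Renan", "Farm-A", 2015, None)
        assert lot.initial_quantity_g is None
        current, _ = st.current_stock(store, lot.name)
        assert current is None

    def test_implausible_year_rejected(self, store):
        with pytest.raises(st.ValidationError):
            store.create_seed_lot("Renan", "Farm-A", 1492)

    def test_quantities_kept_at_decigram_resolution(self, store):
        lot = store.create_seed_lot("Renan", "Farm-A", 2015, 123.456)
        assert lot.initial_quantity_g == 123.5


class TestGraphInvariants:
    def test_cycle_rejected(self, store, repro_chain):
        child = repro_chain["r1"].children[0].name
        origin = repro_chain["origin"].name
        event = repro_chain["r1"].event.event_id
        with pytest.raises(st.CycleError):
            store.add_relation(child, origin, event)

    def test_self_relation_rejected(self, store, renan_lot, repro_chain):
        with pytest.raises((st.ValidationError, st.CycleError)):
            store.add_relation(renan_lot.name, renan_lot.name, repro_chain["r1"].event.event_id)

    def test_referential_integrity_enforced(self, store, renan_lot):
        with pytest.raises(st.UnknownLotError):
            store.add_relation(renan_lot.name, "ghost", "E1")
        with pytest.raises(st.ValidationError):
            store.add_raw_data("lot", renan_lot.name, "unregistered_variable", "1")

    def test_origin_lot_deletion_requires_relation_free(self, store, repro_chain):
        with pytest.raises(st.ValidationError):
            store.delete_origin_lot(repro_chain["origin"].name)
        lonely = store.create_seed_lot("Renan", "Farm-B", 2018)
        store.delete_origin_lot(lonely.name)
        assert lonely.name not in store.lots


class TestPersistence:
    def test_sqlite_roundtrip_byte_identical(self, tmp_path, store, repro_chain):
        store.register(st.Variable("tkw", level="global"))
        rel = repro_chain["r1"].relations[0]
        store.add_raw_data("relation", rel.relation_id, "tkw", "43.1", date=st.FlexDate(2016, 8, 1))
        store.add_inventory(repro_chain["origin"].name, st.FlexDate(2016, 12, 1), 600)
        path = tmp_path / "net.db"
        store.save(path)
        reloaded = st.Store.load(path)
        assert reloaded.dumps() == store.dumps()
        # and the re-dump of a re-save is stable too
        path2 = tmp_path / "net2.db"
        reloaded.save(path2)
        assert st.Store.load(path2).dumps() == store.dumps()

    def test_loaded_store_stays_usable(self, tmp_path, store, repro_chain):
        path = tmp_path / "net.db"
        store.save(path)
        reloaded = st.Store.load(path)
        reloaded.validate_integrity()
        result = st.record_event(
            reloaded,
            st.EventSpec(
                "reproduction",
                st.FlexDate(2018, 10, 20),
                "Farm-B",
                parents=[(repro_chain["r3"].children[0].name, 100)],
            ),
        )
        assert result.event.event_id not in store.events  # fresh id continues the sequence
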