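"""Stock ledger: replay, inventory resets, warnings, determinism."""

import random

import pytest
from hypothesis import given, settings, strategies as hst

import seedtrace as st
from conftest import make_reproduction


def debit(store, lot, grams, date):
    """Helper: a diffusion event whose only ledger effect is a debit."""
    return st.record_diffusion(store, lot, "Farm-B", "Bob", grams, date)


class TestReplay:
    def test_initial_only(self, store, renan_lot):
        entries, warnings = st.stock_history(store, renan_lot.name)
        assert [(e.kind, e.balance_after_g) for e in entries] == [("initial", 1000)]
        assert warnings == []

    def test_debit_inventory_debit_sequence(self, store, renan_lot):
        debit(store, renan_lot.name, 300, st.FlexDate(2016, 8, 1))
        store.add_inventory(renan_lot.name, st.FlexDate(2016, 12, 1), 600)
        debit(store, renan_lot.name, 100, st.FlexDate(2017, 3, 1))
        entries, _ = st.stock_history(store, renan_lot.name)
        assert [e.balance_after_g for e in entries] == [1000, 700, 600, 500]

    def test_as_of_cuts_history(self, store, renan_lot):
        debit(store, renan_lot.name, 300, st.FlexDate(2016, 8, 1))
        store.add_inventory(renan_lot.name, st.FlexDate(2016, 12, 1), 600)
        debit(store, renan_lot.name, 100, st.FlexDate(2017, 3, 1))
        current, _ = st.current_stock(store, renan_lot.name, as_of=st.FlexDate(2016, 12, 15))
        assert current == 600

    def test_as_of_before_first_entry_unknown(self, store, renan_lot):
        current, _ = st.current_stock(store, renan_lot.name, as_of=st.FlexDate(2014, 1, 1))
        assert current is None

    def test_unknown_initial_goes_negative_with_warnings(self, store):
        lot = store.create_seed_lot("Renan", "Farm-A", 2015, None)
        debit(store, lot.name, 200, st.FlexDate(2016, 8, 1))
        entries, warnings = st.stock_history(store, lot.name)
        assert entries[-1].balance_after_g == -200
        assert st.ledger.WARN_UNKNOWN_INITIAL in warnings
        assert st.ledger.WARN_NEGATIVE in warnings

    def test_negative_balance_never_clamped(self, store, renan_lot):
        debit(store, renan_lot.name, 1500, st.FlexDate(2016, 8, 1))
        current, warnings = st.current_stock(store, renan_lot.name)
        assert current == -500
        assert st.ledger.WARN_NEGATIVE in warnings

    def test_same_date_order_initial_debit_inventory(self, store):
        lot = store.create_seed_lot("Renan", "Farm-A", 2016, 1000)
        # initial pins to July 1 of the creation year; same-day debit and inventory
        debit(store, lot.name, 100, st.FlexDate(2016, 7, 1))
        store.add_inventory(lot.name, st.FlexDate(2016, 7, 1), 850)
        entries, _ = st.stock_history(store, lot.name)
        assert [e.kind for e in entries] == ["initial", "debit", "inventory"]
        assert entries[-1].balance_after_g == 850


class TestProperties:
    def test_insertion_order_irrelevant(self, store, renan_lot):
        dates = [st.FlexDate(2016, m, 1) for m in (3, 5, 8, 11)]
        rng = random.Random(7)
        shuffled = dates[:]
        rng.shuffle(shuffled)
        for d in shuffled:
            debit(store, renan_lot.name, 50, d)
        entries, _ = st.stock_history(store, renan_lot.name)
        assert [e.date for e in entries[1:]] == dates
        assert [e.balance_after_g for e in entries] == [1000, 950, 900, 850, 800]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        initial=hst.integers(min_value=0, max_value=5000),
        debits=hst.lists(hst.integers(min_value=0, max_value=400), max_size=8),
    )
    def test_closed_form_without_inventory(self, initial, debits):
        store = st.Store()
        store.register(st.Location("Farm-A"))
        store.register(st.Location("Farm-B"))
        store.register(st.Person("Bob", location="Farm-B"))
        store.register(st.Germplasm("Renan", "Triticum aestivum"))
        lot = store.create_seed_lot("Renan", "Farm-A", 2015, initial)
        for i, grams in enumerate(debits):
            debit(store, lot.name, grams, st.FlexDate(2016, 1 + i % 12, 1 + i))
        current, _ = st.current_stock(store, lot.name)
        assert current == round(initial - sum(debits), 1)

    def test_inventory_dominance(self, store, renan_lot):
        # entries before the inventory are irrelevant to balances at or after it
        debit(store, renan_lot.name, 123, st.FlexDate(2016, 3, 1))
        debit(store, renan_lot.name, 456, st.FlexDate(2016, 4, 1))
        store.add_inventory(renan_lot.name, st.FlexDate(2016, 6, 1), 777)
        debit(store, renan_lot.name, 100, st.FlexDate(2016, 9, 1))
        current, _ = st.current_stock(store, renan_lot.name)
        assert current == 677  # 777 - 100, earlier debits gone

    def test_harvest_does_not_credit_parent(self, store, renan_lot):
        make_reproduction(store, renan_lot.name, "Farm-A", 2015, sown_g=150, harvested_g=3000)
        current, _ = st.current_stock(store, renan_lot.name)
        assert current == 850  # only the sowing debit; harvest goes to the child

    def test_history_tsv_export(self, store, renan_lot):
        debit(store, renan_lot.name, 300, st.FlexDate(2016, 8, 1))
        text = st.history_tsv(store, renan_lot.name)
        lines = text.strip().split("\n")
        assert lines[0] == "date\tkind\tamount_g\tbalance_after_g\tsource"
        assert len(lines) == 3
        assert lines[-1].split("\t")[3] == "700"
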