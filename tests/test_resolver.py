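"""Entity resolution: cascades, indices, xref bridging, reports."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from kgforge.graph import GraphStore
from kgforge.resolver import (
    MappingCascade,
    MappingStrategy,
    Resolver,
    XrefTable,
    build_identifier_index,
    mapping_report,
    normalize_name,
    resolve,
    resolve_via_xref,
)


class TestNormalizeName:
    @pytest.mark.parametrize(
        "raw, expected",
        [("  Aspirin ", "aspirin"), ("Beta—blocker;", "betablocker"),
         ("a   b\tc", "a b c")],
    )
    def test_examples(self, raw, expected):
        assert normalize_name(raw) == expected

    def test_case_variants_collide(self):
        assert normalize_name("Warfarin") == normalize_name("warfarin")

    @settings(max_examples=1000, derandomize=True)
    @given(st.text(max_size=40))
    def test_idempotent(self, text):
        assert normalize_name(normalize_name(text)) == normalize_name(text)


def _compound_store():
    store = GraphStore()
    store.add_node(["Compound"], {"identifier": "DB1", "name": "alpha",
                                  "cas": "1-1", "umls_id": "C9"})
    store.add_node(["Compound"], {"identifier": "DB2", "name": "beta",
                                  "cas": "2-2", "synonyms": ["alfa", "second"]})
    store.add_node(["Compound"], {"identifier": "DB3", "name": "gamma"})
    return store


class TestIdentifierIndex:
    def test_only_keyed_nodes_indexed(self):
        index = build_identifier_index(_compound_store(), "Compound", "cas")
        assert set(index) == {"1-1", "2-2"}

    def test_shared_values_preserve_ambiguity(self):
        store = _compound_store()
        store.add_node(["Compound"], {"identifier": "DB4", "cas": "1-1"})
        index = build_identifier_index(store, "Compound", "cas")
        assert len(index["1-1"]) == 2

    def test_matches_scan_built_map(self):
        rng = random.Random(9)
        store = GraphStore()
        for i in range(120):
            store.add_node(
                ["Gene"], {"identifier": str(i), "symbol": f"S{rng.randrange(40)}"}
            )
        index = build_identifier_index(store, "Gene", "symbol")
        scan = {}
        for node in store.nodes_with_label("Gene"):
            scan.setdefault(node.properties["symbol"], set()).add(node.node_id)
        assert index == scan


class TestResolve:
    def test_first_matching_strategy_wins(self):
        store = GraphStore()
        store.add_node(["Compound"], {"identifier": "DB1", "name": "other"})
        store.add_node(["Compound"], {"identifier": "DB2", "name": "aspirin"})
        cascade = MappingCascade(
            "drug", "Compound",
            (MappingStrategy("identifier", "drugbank_id", "identifier"),
             MappingStrategy("name", "name")),
        )
        result = resolve(
            {"identifier": "x", "drugbank_id": "DB1", "name": "aspirin"},
            cascade, store,
        )
        assert result.status == "unique"
        assert store.nodes[result.node_id].identifier == "DB1"
        assert result.strategy.kind == "identifier"

    def test_synonym_collision_reports_ambiguity(self):
        store = GraphStore()
        store.add_node(["Compound"], {"identifier": "DB1", "synonyms": ["dual"]})
        store.add_node(["Compound"], {"identifier": "DB2", "synonyms": ["dual"]})
        cascade = MappingCascade(
            "drug", "Compound", (MappingStrategy("name", "name"),)
        )
        result = resolve({"identifier": "x", "name": "dual"}, cascade, store)
        assert result.status == "ambiguous"
        assert len(result.matched) == 2

    def test_entity_without_keys_is_unmatched(self):
        cascade = MappingCascade(
            "drug", "Compound",
            (MappingStrategy("identifier", "cas"),),
        )
        result = resolve({"identifier": "x"}, cascade, _compound_store())
        assert result.status == "unmatched" and result.matched == []

    def test_agrees_with_brute_force_scan(self):
        rng = random.Random(13)
        store = GraphStore()
        for i in range(500):
            props = {"identifier": f"N{i}"}
            if rng.random() < 0.7:
                props["cas"] = f"cas{rng.randrange(350)}"
            store.add_node(["Compound"], props)
        cascade = MappingCascade(
            "chem", "Compound", (MappingStrategy("identifier", "cas"),)
        )
        resolver = Resolver(store)
        for probe in range(80):
            entity = {"identifier": f"e{probe}", "cas": f"cas{rng.randrange(380)}"}
            got = resolver.resolve(entity, cascade)
            scan = sorted(
                n.node_id for n in store.nodes_with_label("Compound")
                if n.properties.get("cas") == entity["cas"]
            )
            assert got.matched == scan

    def test_removing_later_strategy_never_changes_earlier_matches(self):
        store = _compound_store()
        full = MappingCascade(
            "drug", "Compound",
            (MappingStrategy("identifier", "cas"), MappingStrategy("name", "name")),
        )
        head = MappingCascade("drug", "Compound", full.strategies[:1])
        entity = {"identifier": "x", "cas": "1-1", "name": "beta"}
        assert resolve(entity, full, store).matched == resolve(entity, head, store).matched

    def test_deterministic_given_store_and_cascade(self):
        store = _compound_store()
        cascade = MappingCascade("d", "Compound", (MappingStrategy("name", "name"),))
        entity = {"identifier": "x", "name": "alfa"}
        assert resolve(entity, cascade, store) == resolve(entity, cascade, store)


class TestXref:
    def test_bridged_identifier_hits_index(self):
        table = XrefTable("meddra", "umls", [("M1", "C1"), ("M2", "C2")])
        index = {"C1": {"n0"}}
        assert resolve_via_xref("M1", table, index) == ["n0"]

    def test_absent_identifier_yields_empty(self):
        table = XrefTable("meddra", "umls", [("M1", "C1")])
        assert resolve_via_xref("M9", table, {"C1": {"n0"}}) == []

    def test_candidates_equal_two_step_join_oracle(self):
        rng = random.Random(21)
        pairs = [(f"M{rng.randrange(15)}", f"C{rng.randrange(15)}")
                 for _ in range(60)]
        index = {
            f"C{i}": {f"n{i}a", f"n{i}b"} for i in range(15) if rng.random() < 0.6
        }
        table = XrefTable("meddra", "umls", pairs)
        for probe in [f"M{i}" for i in range(15)]:
            expected = sorted(
                {node for a, b in set(pairs) if a == probe
                 for node in index.get(b, set())}
            )
            assert resolve_via_xref(probe, table, index) == expected

    def test_self_loops_and_duplicates_dropped(self):
        table = XrefTable("a", "b", [("x", "x"), ("m", "c"), ("m", "c")])
        assert table.bridge("x") == []
        assert table.bridge("m") == ["c"]


class TestMappingReport:
    def test_counts_sum_to_number_of_inputs(self):
        store = _compound_store()
        cascade = MappingCascade(
            "d", "Compound", (MappingStrategy("identifier", "cas"),)
        )
        resolver = Resolver(store)
        results = [
            resolver.resolve({"identifier": str(i), "cas": cas}, cascade)
            for i, cas in enumerate(["1-1", "2-2", "9-9", ""])
        ]
        report = mapping_report(results, store)
        assert sum(report["total"].values()) == 4
        assert report["total"]["unique"] == 2

    def test_differing_names_listed_for_review(self):
        store = GraphStore()
        store.add_node(["Compound"], {"identifier": "DB1", "name": "warfarin",
                                      "cas": "81-81-2"})
        cascade = MappingCascade(
            "d", "Compound", (MappingStrategy("identifier", "cas"),)
        )
        result = resolve(
            {"identifier": "m1", "cas": "81-81-2", "name": "warfarin sodium"},
            cascade, store,
        )
        report = mapping_report([result], store)
        assert len(report["review"]) == 1
        assert report["review"][0]["node_name"] == "warfarin"

    def test_all_unmatched_gives_zero_filled_table(self):
        report = mapping_report([], None)
        assert report["total"] == {"unique": 0, "ambiguous": 0, "unmatched": 0}
        assert report["review"] == []
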