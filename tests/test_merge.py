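"""Schema merge operations: renames, replacement, edge-nodes, hierarchies."""

import random

import pandas as pd
import pytest

from kgforge.errors import ContractError, ForgeError
from kgforge.graph import GraphStore
from kgforge.merge import (
    LabelHierarchy,
    MergePlan,
    apply_label_hierarchy,
    apply_renames,
    create_edge_node,
    generate_allele_edges,
    generate_equal_edges,
    merge_edge,
    replace_or_remove_nodes,
    run_merge,
)


class TestRenames:
    def test_old_types_rewritten(self, small_store):
        store = GraphStore()
        c = store.add_node(["Compound"], {"identifier": "DB1"})
        s = store.add_node(["SideEffect"], {"identifier": "C1"})
        for _ in range(3):
            store.add_edge("CAUSES_CcSE", c, s)
        assert apply_renames(store) == 3
        assert {e.type_name for e in store.edges.values()} == {"CAUSES_CHcSE"}

    def test_empty_map_is_identity(self, small_store):
        before = {e.edge_id: e.type_name for e in small_store.edges.values()}
        assert apply_renames(small_store, {}) == 0
        assert {e.edge_id: e.type_name for e in small_store.edges.values()} == before

    def test_per_type_counts_conserved_under_permutation(self):
        rng = random.Random(41)
        store = GraphStore()
        nodes = [store.add_node(["Gene"], {"identifier": str(i)}) for i in range(10)]
        types = ["A_GaG", "B_GbG", "C_GcG"]
        for _ in range(60):
            store.add_edge(rng.choice(types), rng.choice(nodes), rng.choice(nodes))
        before = {t: len(store.edges_of_type(t)) for t in types}
        mapping = {"A_GaG": "B_GbG"}
        apply_renames(store, mapping)
        assert len(store.edges_of_type("B_GbG")) == before["A_GaG"] + before["B_GbG"]
        assert len(store.edges_of_type("C_GcG")) == before["C_GcG"]


class TestReplaceOrRemove:
    def _seed(self):
        store = GraphStore()
        d1 = store.add_node(["Disease"], {"identifier": "DOID:1", "name": "a"})
        d2 = store.add_node(["Disease"], {"identifier": "DOID:2", "name": "b"})
        g = store.add_node(["Gene"], {"identifier": "g"})
        store.add_edge("ASSOCIATES_DaG", d1, g)
        store.add_edge("ASSOCIATES_DaG", d2, g)
        return store, d1, d2, g

    def test_replace_remove_create_counts_and_edge_preservation(self):
        store, d1, d2, g = self._seed()
        table = pd.DataFrame(
            [{"identifier": "MONDO:1", "name": "a2", "xrefs": "DOID:1"},
             {"identifier": "MONDO:3", "name": "new", "xrefs": ""}]
        )
        replaced, removed, created = replace_or_remove_nodes(
            store, "Disease", table, match_column="xrefs"
        )
        assert (replaced, removed, created) == (1, 1, 1)
        assert store.nodes[d1].identifier == "MONDO:1"
        assert store.degree(d1) == 1  # edges of the replaced node intact
        assert d2 not in store.nodes  # removed with its edge
        assert store.edge_count() == 1

    def test_full_overlap_changes_nothing_structurally(self):
        store, d1, d2, g = self._seed()
        table = pd.DataFrame(
            [{"identifier": "DOID:1", "name": "a"},
             {"identifier": "DOID:2", "name": "b"}]
        )
        replaced, removed, created = replace_or_remove_nodes(store, "Disease", table)
        assert (replaced, removed, created) == (2, 0, 0)
        assert store.edge_count() == 2

    def test_duplicate_match_keys_rejected(self):
        store, *_ = self._seed()
        table = pd.DataFrame(
            [{"identifier": "M:1", "xrefs": "DOID:1"},
             {"identifier": "M:2", "xrefs": "DOID:1"}]
        )
        with pytest.raises(ContractError, match="duplicate"):
            replace_or_remove_nodes(store, "Disease", table, match_column="xrefs")

    def test_final_sets_match_set_algebra_oracle(self):
        rng = random.Random(43)
        store = GraphStore()
        existing = [f"D{i}" for i in range(30)]
        for ident in existing:
            store.add_node(["Disease"], {"identifier": ident})
        anchor = store.add_node(["Gene"], {"identifier": "g"})
        for ident in existing:
            if rng.random() < 0.5:
                store.add_edge(
                    "ASSOCIATES_DaG",
                    store.lookup("Disease", "identifier", ident)[0], anchor,
                )
        kept = {i for i in existing if rng.random() < 0.6}
        novel = {f"N{i}" for i in range(8)}
        table = pd.DataFrame(
            [{"identifier": i} for i in sorted(kept | novel)]
        )
        degrees_before = {
            i: store.degree(store.lookup("Disease", "identifier", i)[0])
            for i in kept
        }
        replace_or_remove_nodes(store, "Disease", table)
        final = {n.identifier for n in store.nodes_with_label("Disease")}
        assert final == kept | novel  # exactly the replacement key set
        for ident, degree in degrees_before.items():
            node_id = store.lookup("Disease", "identifier", ident)[0]
            assert store.degree(node_id) == degree  # degree preserved


class TestMergeEdge:
    def test_second_identical_merge_updates_not_creates(self, small_store):
        store = small_store
        c = store.lookup("Compound", "identifier", "DB1")[0]
        d = store.lookup("Disease", "identifier", "MONDO:9")[0]
        before = store.edge_count()
        assert merge_edge(store, c, d, "TREATS_CHtD", source="CTD") == "updated"
        assert store.edge_count() == before

    def test_same_endpoints_different_type_creates(self, small_store):
        store = small_store
        c = store.lookup("Compound", "identifier", "DB1")[0]
        d = store.lookup("Disease", "identifier", "MONDO:9")[0]
        assert merge_edge(store, c, d, "PALLIATES_CHpD") == "created"

    def test_duplicate_and_novel_counts_match_pair_set_oracle(self):
        rng = random.Random(47)
        store = GraphStore()
        nodes = [store.add_node(["Gene"], {"identifier": str(i)}) for i in range(8)]
        existing = set()
        for _ in range(15):
            a, b = rng.choice(nodes), rng.choice(nodes)
            if (a, b) not in existing:
                store.add_edge("INTERACTS_GiG", a, b)
                existing.add((a, b))
        candidates = [(rng.choice(nodes), rng.choice(nodes)) for _ in range(30)]
        created = sum(
            merge_edge(store, a, b, "INTERACTS_GiG") == "created"
            for a, b in candidates
        )
        assert created == len(set(candidates) - existing)

    def test_scalar_conflicts_keep_existing_and_tag_incoming(self, small_store):
        store = small_store
        c = store.lookup("Compound", "identifier", "DB1")[0]
        g = store.lookup("Gene", "identifier", "10")[0]
        edge = store.out_edges(c)[0]
        edge.properties["affinity"] = "high"
        merge_edge(
            store, edge.source_id, edge.target_id, edge.type_name,
            {"affinity": "low"}, source="CTD",
        )
        assert edge.properties["affinity"] == "high"
        assert edge.properties["affinity_ctd"] == "low"


class TestEdgeNodes:
    def test_interaction_reification_yields_both_directions(self):
        store = GraphStore()
        p1 = store.add_node(["Protein"], {"identifier": "P1"})
        p2 = store.add_node(["Protein"], {"identifier": "P2"})
        node_id = create_edge_node(
            store, "Interaction",
            [(p1, "INTERACTS_IiP"), (p1, "INTERACTS_PiI"),
             (p2, "INTERACTS_IiP"), (p2, "INTERACTS_PiI")],
            {"identifier": "ia1"},
        )
        out = {(e.type_name, e.target_id) for e in store.out_edges(node_id)}
        into = {(e.type_name, e.source_id) for e in store.in_edges(node_id)}
        assert out == {("INTERACTS_IiP", p1), ("INTERACTS_IiP", p2)}
        assert into == {("INTERACTS_PiI", p1), ("INTERACTS_PiI", p2)}

    def test_treatment_over_three_participants(self):
        store = GraphStore()
        ch = store.add_node(["Chemical"], {"identifier": "c"})
        d = store.add_node(["Disease"], {"identifier": "d"})
        cc = store.add_node(["CellularComponent"], {"identifier": "g"})
        t = create_edge_node(
            store, "Treatment",
            [(ch, "TREATS_CHtT"), (d, "TREATS_TtD"), (cc, "IS_LOCALIZED_IN_TiliCC")],
            {"identifier": "t1"},
        )
        assert {e.type_name for e in store.out_edges(t)} == {
            "TREATS_TtD", "IS_LOCALIZED_IN_TiliCC",
        }
        assert {e.type_name for e in store.in_edges(t)} == {"TREATS_CHtT"}

    def test_node_and_edge_count_arithmetic(self):
        store = GraphStore()
        proteins = [
            store.add_node(["Protein"], {"identifier": f"P{i}"}) for i in range(12)
        ]
        n0, e0 = store.node_count(), store.edge_count()
        for i in range(0, 12, 2):
            create_edge_node(
                store, "Interaction",
                [(proteins[i], "INTERACTS_IiP"), (proteins[i + 1], "INTERACTS_IiP")],
                {"identifier": f"ia{i}"},
            )
        assert store.node_count() == n0 + 6
        assert store.edge_count() == e0 + 12

    def test_fewer_than_two_participants_is_contract_error(self):
        store = GraphStore()
        p = store.add_node(["Protein"], {"identifier": "P1"})
        with pytest.raises(ContractError):
            create_edge_node(store, "Interaction", [(p, "INTERACTS_IiP")], {})


class TestLabelHierarchy:
    def test_salt_closure_reaches_chemical(self):
        store = GraphStore()
        store.add_node(["Salt"], {"identifier": "s"})
        added = apply_label_hierarchy(store)
        assert added == 2
        node = store.nodes_with_label("Salt")[0]
        assert set(node.labels) == {"Salt", "Compound", "Chemical"}

    def test_second_application_adds_nothing(self, pipeline_result):
        assert apply_label_hierarchy(pipeline_result["extracted"].copy()) == 0

    def test_closure_matches_transitive_closure_oracle(self):
        rng = random.Random(53)
        hierarchy = LabelHierarchy()
        store = GraphStore()
        leaves = list(hierarchy.parents)
        for i in range(40):
            store.add_node([rng.choice(leaves)], {"identifier": str(i)})
        apply_label_hierarchy(store, hierarchy)
        for node in store.nodes.values():
            expected = {node.primary_label} | hierarchy.closure(node.primary_label)
            assert set(node.labels) == expected

    def test_cyclic_hierarchy_rejected(self):
        with pytest.raises(ContractError):
            LabelHierarchy({"A": ("B",), "B": ("A",)})


class TestEqualEdges:
    def test_shared_umls_links_disease_to_side_effect(self):
        store = GraphStore()
        d = store.add_node(["Disease", "Phenotype"],
                           {"identifier": "M:1", "umls_id": "C1", "name": "x"})
        s = store.add_node(["SideEffect", "Phenotype"],
                           {"identifier": "C1", "umls_id": "C1", "name": "y"})
        assert generate_equal_edges(store) == 1
        edge = next(iter(store.edges.values()))
        assert (edge.type_name, edge.source_id, edge.target_id) == ("EQUAL_DeSE", d, s)

    def test_no_shared_keys_no_edges(self):
        store = GraphStore()
        store.add_node(["Disease"], {"identifier": "a", "name": "one"})
        store.add_node(["SideEffect"], {"identifier": "b", "name": "two"})
        assert generate_equal_edges(store) == 0

    def test_planted_pairs_match_key_intersection_oracle(self):
        rng = random.Random(59)
        store = GraphStore()
        labels = [("Disease",), ("Symptom",), ("SideEffect",), ("Phenotype",)]
        planted = []
        for i in range(30):
            label = rng.choice(labels)
            umls = f"C{rng.randrange(12)}"
            store.add_node(
                label + ("Phenotype",) if label[0] != "Phenotype" else label,
                {"identifier": f"n{i:02d}", "umls_id": umls, "name": f"name{i}"},
            )
            planted.append((f"n{i:02d}", label[0], umls))
        created = generate_equal_edges(store)
        # oracle: pairs sharing a umls key whose label pair has an EQUAL type
        type_for = {
            frozenset({"Disease", "SideEffect"}), frozenset({"Disease", "Symptom"}),
            frozenset({"Symptom", "SideEffect"}), frozenset({"Phenotype", "SideEffect"}),
        }
        expected = 0
        for i in range(len(planted)):
            for j in range(i + 1, len(planted)):
                a, b = planted[i], planted[j]
                if a[2] != b[2]:
                    continue
                if frozenset({a[1], b[1]}) in type_for:
                    expected += 1
        assert created == expected

    def test_idempotent(self):
        store = GraphStore()
        store.add_node(["Disease", "Phenotype"], {"identifier": "d", "umls_id": "C1"})
        store.add_node(["SideEffect", "Phenotype"], {"identifier": "s", "umls_id": "C1"})
        assert generate_equal_edges(store) == 1
        assert generate_equal_edges(store) == 0


class TestAlleleEdges:
    def test_three_way_group_yields_all_pairs(self):
        store = GraphStore()
        for i in range(3):
            store.add_node(["GeneVariant", "Variant"],
                           {"identifier": f"v{i}", "rs_id": "rs123"})
        assert generate_allele_edges(store) == 3  # C(3, 2)

    def test_unique_rs_ids_yield_nothing(self):
        store = GraphStore()
        for i in range(4):
            store.add_node(["GeneVariant", "Variant"],
                           {"identifier": f"v{i}", "rs_id": f"rs{i}"})
        assert generate_allele_edges(store) == 0

    def test_edges_match_per_group_pair_union_oracle(self):
        rng = random.Random(61)
        store = GraphStore()
        groups = {}
        for i in range(25):
            rs = f"rs{rng.randrange(8)}"
            store.add_node(["GeneVariant", "Variant"],
                           {"identifier": f"v{i:02d}", "rs_id": rs})
            groups.setdefault(rs, []).append(i)
        created = generate_allele_edges(store)
        expected = sum(len(g) * (len(g) - 1) // 2 for g in groups.values())
        assert created == expected
        # deterministic direction: lexicographically smaller identifier first
        for edge in store.edges.values():
            src = store.nodes[edge.source_id].identifier
            dst = store.nodes[edge.target_id].identifier
            assert src < dst


class TestRunMerge:
    def test_noop_plan_reports_zeros_and_leaves_graph_unchanged(self, small_store):
        plan = MergePlan((("nothing", "noop"),))
        report = run_merge(
            small_store, plan, {"noop": lambda store, ctx: {"did": 0}}, None
        )
        assert report["steps"][0]["counts"] == {"did": 0}

    def test_unknown_routine_aborts_with_plan_position(self, small_store):
        plan = MergePlan((("x", "absent"),))
        with pytest.raises(ForgeError, match="step 0"):
            run_merge(small_store, plan, {}, None)

    def test_routine_failure_aborts_with_position(self, small_store):
        def boom(store, ctx):
            raise ValueError("nope")

        plan = MergePlan((("ok", "noop"), ("bad", "boom")))
        routines = {"noop": lambda s, c: {}, "boom": boom}
        with pytest.raises(ForgeError, match="step 1"):
            run_merge(small_store, plan, routines, None)
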