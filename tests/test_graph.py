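"""Property-graph store: table loading, indices, and pattern path search."""

import io
import random

import pandas as pd
import pytest

from kgforge.errors import FormatError
from kgforge.fixtures import fig4_topology, variant_to_drug_pattern
from kgforge.graph import (
    EdgeConstraint,
    GraphStore,
    NodeConstraint,
    PathPattern,
    find_paths,
    load_edge_table,
    load_node_table,
)


def _tsv(text: str) -> io.StringIO:
    return io.StringIO(text)


class TestLoadNodeTable:
    def test_one_node_per_row(self):
        store = GraphStore()
        n = load_node_table(
            _tsv("identifier\tname\nMONDO:1\ta\nMONDO:2\tb\n"), "Disease", store
        )
        assert n == 2
        assert [x.identifier for x in store.nodes_with_label("Disease")] == [
            "MONDO:1", "MONDO:2",
        ]

    def test_header_only_creates_nothing(self):
        store = GraphStore()
        assert load_node_table(_tsv("identifier\tname\n"), "Disease", store) == 0

    def test_missing_identifier_column_is_format_error(self):
        with pytest.raises(FormatError):
            load_node_table(_tsv("name\nx\n"), "Disease", GraphStore())

    def test_duplicate_identifier_rejected_by_default(self):
        with pytest.raises(FormatError):
            load_node_table(
                _tsv("identifier\nG1\nG1\n"), "Gene", GraphStore()
            )

    def test_merge_policy_creates_one_node_per_distinct_identifier(self):
        rng = random.Random(7)
        ids = [f"G{rng.randrange(12)}" for _ in range(40)]
        table = pd.DataFrame({"identifier": ids, "synonyms": ids})
        store = GraphStore()
        created = load_node_table(table, "Gene", store, duplicate_policy="merge")
        assert created == len(set(ids))  # independent set oracle

    def test_list_cells_split_on_delimiter(self):
        store = GraphStore()
        load_node_table(_tsv("identifier\tsynonyms\nG1\ta|b|c\n"), "Gene", store)
        node = store.nodes_with_label("Gene")[0]
        assert node.properties["synonyms"] == ["a", "b", "c"]


class TestLoadEdgeTable:
    def _genes(self, store, idents):
        for ident in idents:
            store.add_node(["Gene"], {"identifier": ident})

    def test_all_endpoints_resolve(self):
        store = GraphStore()
        self._genes(store, ["a", "b", "c"])
        n = load_edge_table(
            _tsv("source_id\ttarget_id\na\tb\nb\tc\na\tc\n"),
            "INTERACTS_GiG", store, "Gene", "Gene",
        )
        assert n == 3

    def test_unknown_endpoint_skipped_and_logged(self, caplog):
        store = GraphStore()
        self._genes(store, ["a", "b"])
        with caplog.at_level("WARNING", logger="kgforge.graph"):
            n = load_edge_table(
                _tsv("source_id\ttarget_id\na\tb\nb\tmissing\nb\ta\n"),
                "INTERACTS_GiG", store, "Gene", "Gene",
            )
        assert n == 2
        assert any("missing" in record.message for record in caplog.records)

    def test_created_count_matches_relational_join_oracle(self):
        rng = random.Random(11)
        idents = [f"g{i}" for i in range(15)]
        store = GraphStore()
        self._genes(store, idents)
        rows = pd.DataFrame(
            {
                "source_id": [rng.choice(idents + ["zz"]) for _ in range(60)],
                "target_id": [rng.choice(idents + ["yy"]) for _ in range(60)],
            }
        )
        known = pd.DataFrame({"identifier": idents})
        resolvable = rows.merge(
            known, left_on="source_id", right_on="identifier"
        ).merge(known, left_on="target_id", right_on="identifier")
        created = load_edge_table(rows, "INTERACTS_GiG", store, "Gene", "Gene")
        assert created == len(resolvable)
        # no dangling edges
        assert all(
            e.source_id in store.nodes and e.target_id in store.nodes
            for e in store.edges.values()
        )


class TestIndices:
    def test_lookup_agrees_with_linear_scan(self):
        rng = random.Random(3)
        store = GraphStore()
        for i in range(80):
            store.add_node(
                ["Gene"], {"identifier": str(i), "group": str(rng.randrange(6))}
            )
        for value in map(str, range(6)):
            scan = sorted(
                n.node_id for n in store.nodes_with_label("Gene")
                if n.properties.get("group") == value
            )
            assert store.lookup("Gene", "group", value) == scan

    def test_index_entries_follow_node_removal_and_update(self):
        store = GraphStore()
        a = store.add_node(["Gene"], {"identifier": "1"})
        store.add_node(["Gene"], {"identifier": "2"})
        assert store.lookup("Gene", "identifier", "1") == [a]
        store.set_properties(a, {"identifier": "9"})
        assert store.lookup("Gene", "identifier", "1") == []
        assert store.lookup("Gene", "identifier", "9") == [a]
        store.remove_node(a)
        assert store.lookup("Gene", "identifier", "9") == []

    def test_list_valued_properties_index_each_element(self):
        store = GraphStore()
        n = store.add_node(["Disease"], {"identifier": "D", "xrefs": ["A:1", "B:2"]})
        assert store.lookup("Disease", "xrefs", "A:1") == [n]
        assert store.lookup("Disease", "xrefs", "B:2") == [n]


def _enumerate_walks(store, pattern):
    """Independent brute-force walk enumeration (no index, no ordering)."""
    from kgforge.graph import _node_matches

    steps = pattern.steps
    results = []

    def extend(node_id, idx, trail):
        if idx == len(steps):
            results.append(tuple(trail))
            return
        constraint = steps[idx]
        candidates = []
        if constraint.direction in ("out", "any"):
            candidates += [(e, e.target_id) for e in store.out_edges(node_id)]
        if constraint.direction in ("in", "any"):
            candidates += [(e, e.source_id) for e in store.in_edges(node_id)]
        for edge, neighbor in candidates:
            if constraint.type_name and edge.type_name != constraint.type_name:
                continue
            if _node_matches(store.nodes[neighbor], steps[idx + 1]):
                extend(neighbor, idx + 2, trail + [edge.edge_id, neighbor])

    for node in store.nodes.values():
        if _node_matches(node, steps[0]):
            extend(node.node_id, 1, [node.node_id])
    return sorted(results)


class TestFindPaths:
    def test_pharmacogenomic_topology_yields_one_path_per_variant(self):
        store = fig4_topology()
        paths = find_paths(store, variant_to_drug_pattern("DB00682"))
        assert len(paths) == 3
        starts = {store.nodes[p[0]].identifier for p in paths}
        assert starts == {"VCV000634", "VCV000636", "VCV000639"}

    def test_empty_graph_returns_empty_list(self):
        pattern = PathPattern(
            (NodeConstraint.of("Gene"), EdgeConstraint(None, "out"),
             NodeConstraint.of())
        )
        assert find_paths(GraphStore(), pattern) == []

    def test_matches_exhaustive_walk_enumeration(self):
        rng = random.Random(5)
        store = GraphStore()
        labels = ["Gene", "Protein", "Chemical"]
        nodes = [
            store.add_node([rng.choice(labels)], {"identifier": f"n{i:02d}"})
            for i in range(25)
        ]
        for _ in range(60):
            store.add_edge(
                rng.choice(["BINDS_CHbP", "PRODUCES_GpP"]),
                rng.choice(nodes), rng.choice(nodes),
            )
        pattern = PathPattern(
            (
                NodeConstraint.of("Gene"),
                EdgeConstraint("PRODUCES_GpP", "out"),
                NodeConstraint.of(),
                EdgeConstraint(None, "any"),
                NodeConstraint.of(),
            )
        )
        got = sorted(tuple(p) for p in find_paths(store, pattern))
        assert got == _enumerate_walks(store, pattern)

    def test_max_results_truncates_deterministically(self):
        store = fig4_topology()
        pattern = variant_to_drug_pattern("DB00682")
        all_paths = find_paths(store, pattern)
        assert find_paths(store, pattern, max_results=2) == all_paths[:2]
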