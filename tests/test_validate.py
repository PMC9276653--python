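"""Technical validators and final merged-subgraph extraction."""

import random

from kgforge.graph import GraphStore
from kgforge.validate import (
    check_human_only,
    extract_indices,
    extract_merged_subgraph,
    validate_edge_names,
    validate_resource_tags,
)


class TestEdgeNameValidator:
    def test_pipeline_built_graph_has_zero_violations(self, pipeline_result):
        report = validate_edge_names(pipeline_result["extracted"])
        assert report.passed and report.checked > 100

    def test_label_mismatch_detected(self, small_store):
        store = small_store
        c = store.lookup("Compound", "identifier", "DB1")[0]
        d = store.lookup("Disease", "identifier", "MONDO:9")[0]
        store.add_edge("TREATS_GtD", c, d)  # source abbreviation says Gene
        report = validate_edge_names(store)
        assert len(report.violations) == 1
        assert "source abbreviation" in report.violations[0][2]

    def test_corrupting_k_edge_types_yields_k_violations(self, pipeline_result):
        rng = random.Random(67)
        store = pipeline_result["extracted"].copy()
        edge_ids = rng.sample(sorted(store.edges), 7)
        for edge_id in edge_ids:
            store.edges[edge_id].type_name = "BOGUS_XXxXX"
        report = validate_edge_names(store)
        assert len(report.violations) == 7

    def test_phenotype_alias_for_irregular_omim_edge(self):
        store = GraphStore()
        p = store.add_node(["Phenotype"], {"identifier": "OMIM:1"})
        g = store.add_node(["Gene"], {"identifier": "1"})
        store.add_edge("ASSOCIATES_PaG", p, g)
        assert validate_edge_names(store).passed


class TestResourceTagValidator:
    def test_tagged_node_passes(self):
        store = GraphStore()
        store.add_node(["Chemical"],
                       {"identifier": "x", "resource": ["CTD"], "ctd_id": "m1"})
        assert validate_resource_tags(store).passed

    def test_missing_tag_is_violation(self):
        store = GraphStore()
        store.add_node(["Chemical"], {"identifier": "x", "resource": ["CTD"]})
        report = validate_resource_tags(store)
        assert len(report.violations) == 1
        assert "CTD" in report.violations[0][2]

    def test_planted_missing_tags_counted_exactly(self, pipeline_result):
        rng = random.Random(71)
        store = pipeline_result["extracted"].copy()
        tagged = [
            n for n in store.nodes.values()
            if isinstance(n.properties.get("resource"), list)
        ]
        victims = rng.sample(tagged, 5)
        for node in victims:
            node.properties["resource"] = node.properties["resource"] + ["Phantom"]
        report = validate_resource_tags(store)
        assert len(report.violations) == 5


class TestHumanOnly:
    def test_human_gene_passes_mouse_gene_fails(self):
        store = GraphStore()
        store.add_node(["Gene"], {"identifier": "1", "taxon_id": "9606"})
        store.add_node(["Gene"], {"identifier": "2", "taxon_id": "10090"})
        report = check_human_only(store)
        assert len(report.violations) == 1
        assert "10090" in report.violations[0][2]

    def test_nodes_without_taxon_not_flagged(self):
        store = GraphStore()
        store.add_node(["SideEffect"], {"identifier": "C1"})
        assert check_human_only(store).passed

    def test_violations_match_non_human_count_oracle(self):
        rng = random.Random(73)
        store = GraphStore()
        taxa = [rng.choice([9606, 9606, 10090, 7227]) for _ in range(40)]
        for i, taxon in enumerate(taxa):
            store.add_node(["Protein"], {"identifier": f"P{i}", "taxon_id": taxon})
        report = check_human_only(store)
        assert len(report.violations) == sum(1 for t in taxa if t != 9606)


class TestExtraction:
    def _mixed(self):
        store = GraphStore()
        merged = [
            store.add_node(["Gene"], {"identifier": f"g{i}"}) for i in range(5)
        ]
        sourced = [
            store.add_node(["ctd__gene"], {"identifier": f"s{i}", "source": "ctd"})
            for i in range(7)
        ]
        store.add_edge("INTERACTS_GiG", merged[0], merged[1])
        store.add_edge("ctd__raw", sourced[0], sourced[1])
        store.add_edge("INTERACTS_GiG", merged[2], sourced[2])  # would dangle
        return store, merged, sourced

    def test_source_marked_entities_dropped(self):
        store, merged, _ = self._mixed()
        out = extract_merged_subgraph(store)
        assert out.node_count() == 5
        assert set(out.nodes) == set(merged)
        assert out.edge_count() == 1  # dangling edge dropped with its endpoint
        assert store.node_count() == 12  # input untouched

    def test_all_merged_graph_copies_identically(self, small_store):
        out = extract_merged_subgraph(small_store)
        assert set(out.nodes) == set(small_store.nodes)
        assert set(out.edges) == set(small_store.edges)

    def test_extraction_is_idempotent(self, pipeline_result):
        extracted = pipeline_result["extracted"]
        again = extract_merged_subgraph(extracted)
        assert set(again.nodes) == set(extracted.nodes)
        assert set(again.edges) == set(extracted.edges)

    def test_random_partition_matches_predicate_filter_oracle(self):
        rng = random.Random(79)
        store = GraphStore()
        nodes = []
        for i in range(50):
            props = {"identifier": f"n{i}"}
            if rng.random() < 0.4:
                props["source"] = "src"
            nodes.append(store.add_node(["Gene"], props))
        for _ in range(120):
            store.add_edge("INTERACTS_GiG", rng.choice(nodes), rng.choice(nodes))
        out = extract_merged_subgraph(store)
        kept = {
            n for n in nodes if "source" not in store.nodes[n].properties
        }
        assert set(out.nodes) == kept
        expected_edges = {
            e.edge_id for e in store.edges.values()
            if e.source_id in kept and e.target_id in kept
        }
        assert set(out.edges) == expected_edges

    def test_indices_filtered_to_surviving_labels(self):
        store, merged, _ = self._mixed()
        store.create_index("Gene", "identifier")
        store.create_index("ctd__gene", "identifier")
        out = extract_merged_subgraph(store)
        assert extract_indices(out) == [("Gene", "identifier")]
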