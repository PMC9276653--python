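"""Per-source filter catalogue, deduplication, and the adapter runner."""

import random

import pandas as pd
import pytest

from kgforge.adapters import (
    EVIDENCE_CODES,
    bundled_adapter_registry,
    dedupe_entities,
    filter_annotation_evidence,
    filter_by_taxon,
    filter_direct_evidence,
    filter_evidence_contains,
    filter_in_identifier_list,
    filter_outcome_pairs,
    filter_requires_reference,
    filter_source_whitelist,
    prune_disconnected,
    run_adapter,
    translate_evidence_code,
)


class TestTaxonFilter:
    def test_archaic_subspecies_rows_removed(self):
        rows = pd.DataFrame({"tax_id": ["9606", "63221", "741158", "9606"]})
        out = filter_by_taxon(rows, "tax_id")
        assert list(out.tax_id) == ["9606", "9606"]

    def test_all_human_is_identity(self):
        rows = pd.DataFrame({"tax_id": ["9606"] * 4, "g": list("abcd")})
        assert filter_by_taxon(rows, "tax_id").equals(rows)

    def test_survivors_match_column_count_oracle(self):
        rng = random.Random(1)
        taxa = [rng.choice(["9606", "10090", "63221"]) for _ in range(100)]
        out = filter_by_taxon(pd.DataFrame({"tax_id": taxa}), "tax_id")
        assert len(out) == taxa.count("9606")

    def test_non_integer_cells_rejected_and_logged(self, caplog):
        rows = pd.DataFrame({"tax_id": ["9606", "human"]})
        with caplog.at_level("WARNING", logger="kgforge.adapters"):
            out = filter_by_taxon(rows, "tax_id")
        assert len(out) == 1 and "human" in caplog.text


class TestOutcomePairFilter:
    def test_default_thresholds_probed_behaviorally(self):
        rows = pd.DataFrame(
            {"frequency": ["0.2", "0.2", "0.05", "0.1"],
             "report_count": ["150", "50", "150", "100"]}
        )
        out = filter_outcome_pairs(rows)
        # inclusive bounds: (0.2, 150) and the exact boundary (0.1, 100) survive
        assert list(out.index) == [0, 1]
        assert list(out.frequency) == ["0.2", "0.1"]

    def test_grid_matches_brute_force_predicate(self):
        rng = random.Random(2)
        freq = [round(rng.uniform(0, 0.3), 3) for _ in range(20)]
        count = [rng.randrange(0, 300) for _ in range(20)]
        rows = pd.DataFrame({"frequency": freq, "report_count": count})
        out = filter_outcome_pairs(rows.astype(str))
        expected = [
            i for i in range(20) if freq[i] >= 0.1 and count[i] >= 100
        ]
        assert [int(i) for i in out.index] == list(range(len(expected)))
        assert len(out) == len(expected)

    def test_negative_values_rejected(self, caplog):
        rows = pd.DataFrame({"frequency": ["-1"], "report_count": ["5"]})
        with caplog.at_level("WARNING", logger="kgforge.adapters"):
            assert filter_outcome_pairs(rows).empty


class TestAnnotationEvidenceFilter:
    def test_levels_one_to_three_survive(self):
        rows = pd.DataFrame(
            {"evidence_level": ["1", "2", "3", "4"], "significance": [""] * 4}
        )
        out = filter_annotation_evidence(rows)
        assert list(out.evidence_level) == ["1", "2", "3"]

    def test_only_significant_variant_annotations_survive(self):
        rows = pd.DataFrame(
            {"evidence_level": ["", ""], "significance": ["yes", "no"]}
        )
        out = filter_annotation_evidence(rows)
        assert list(out.significance) == ["yes"]

    def test_random_table_matches_set_membership_oracle(self):
        rng = random.Random(3)
        levels = [rng.choice(["1", "2", "3", "4", ""]) for _ in range(50)]
        sig = ["" if l else rng.choice(["yes", "no"]) for l in levels]
        out = filter_annotation_evidence(
            pd.DataFrame({"evidence_level": levels, "significance": sig})
        )
        expected = sum(
            1 for l, s in zip(levels, sig)
            if (l in {"1", "2", "3"}) or (not l and s == "yes")
        )
        assert len(out) == expected

    def test_unparseable_level_rejected(self, caplog):
        rows = pd.DataFrame({"evidence_level": ["high"], "significance": [""]})
        with caplog.at_level("WARNING", logger="kgforge.adapters"):
            assert filter_annotation_evidence(rows).empty


class TestSimpleFilters:
    def test_direct_evidence_drops_blank_cells(self):
        rows = pd.DataFrame({"DirectEvidence": ["therapeutic", "", "  ", "marker"]})
        assert len(filter_direct_evidence(rows, "DirectEvidence")) == 2

    def test_requires_reference_drops_empty_lists(self):
        rows = pd.DataFrame({"refs": ["1|2", "", "3"]})
        assert len(filter_requires_reference(rows, "refs")) == 2

    def test_source_whitelist_keeps_licensed_providers(self):
        rows = pd.DataFrame({"db": ["Reactome", "KEGG", "Panther"]})
        assert list(filter_source_whitelist(rows, "db").db) == ["Reactome", "Panther"]

    def test_evidence_contains_token_membership(self):
        rows = pd.DataFrame({"ev": ["exp", "pred", "exp|pred", "exptl"]})
        assert len(filter_evidence_contains(rows, "ev")) == 2

    def test_identifier_semi_join(self):
        rows = pd.DataFrame({"uniprot": ["P1", "P2", "P3"]})
        out = filter_in_identifier_list(rows, "uniprot", {"P1", "P3"})
        assert list(out.uniprot) == ["P1", "P3"]

    @pytest.mark.parametrize(
        "fn, kwargs",
        [
            (filter_by_taxon, {"taxon_column": "tax_id"}),
            (filter_direct_evidence, {"evidence_column": "DirectEvidence"}),
            (filter_outcome_pairs, {}),
            (filter_requires_reference, {"reference_column": "refs"}),
            (filter_evidence_contains, {"evidence_column": "ev"}),
        ],
    )
    def test_filters_are_idempotent(self, fn, kwargs):
        rng = random.Random(4)
        rows = pd.DataFrame(
            {
                "tax_id": [rng.choice(["9606", "10090"]) for _ in range(30)],
                "DirectEvidence": [rng.choice(["x", ""]) for _ in range(30)],
                "frequency": [str(round(rng.uniform(0, 0.3), 2)) for _ in range(30)],
                "report_count": [str(rng.randrange(300)) for _ in range(30)],
                "refs": [rng.choice(["1", ""]) for _ in range(30)],
                "ev": [rng.choice(["exp", "pred"]) for _ in range(30)],
            }
        )
        once = fn(rows, **kwargs)
        twice = fn(once, **kwargs)
        assert once.equals(twice)


class TestEvidenceCodes:
    def test_experimental_code_translates(self):
        assert translate_evidence_code("EXP") == "Inferred from Experiment"

    def test_unknown_code_passes_through_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="kgforge.adapters"):
            assert translate_evidence_code("ZZZ") == "ZZZ"
        assert "ZZZ" in caplog.text

    def test_bundled_table_is_injective_and_non_empty(self):
        values = list(EVIDENCE_CODES.values())
        assert all(values)
        assert len(values) == len(set(values))


class TestDedupe:
    def test_list_columns_unioned_across_duplicates(self):
        rows = pd.DataFrame(
            {"id": ["P1", "P1"], "synonyms": ["a|b", "b|c"], "name": ["x", "y"]}
        )
        out = dedupe_entities(rows, ["id"])
        assert len(out) == 1
        assert out.loc[0, "synonyms"] == "a|b|c"
        assert out.loc[0, "name"] == "x"  # first occurrence wins

    def test_no_duplicates_is_identity(self):
        rows = pd.DataFrame({"id": ["a", "b"], "v": ["1", "2"]})
        assert dedupe_entities(rows, ["id"]).equals(rows)

    def test_row_count_equals_distinct_key_count(self):
        rng = random.Random(5)
        keys = [f"k{rng.randrange(9)}" for _ in range(50)]
        rows = pd.DataFrame({"id": keys, "v": keys})
        assert len(dedupe_entities(rows, ["id"])) == len(set(keys))


class TestPruneDisconnected:
    def test_connected_nodes_survive(self):
        nodes = {"Gene": pd.DataFrame({"identifier": ["g1", "g2", "g3"]})}
        edges = [(pd.DataFrame({"source_id": ["g1"], "target_id": ["g2"]}),
                  "Gene", "Gene")]
        out = prune_disconnected(nodes, edges, {"Gene"})
        assert list(out["Gene"].identifier) == ["g1", "g2"]

    def test_keep_labels_never_pruned(self):
        nodes = {"Chemical": pd.DataFrame({"identifier": ["c1"]})}
        out = prune_disconnected(nodes, [], {"Chemical"}, keep_labels={"Chemical"})
        assert list(out["Chemical"].identifier) == ["c1"]

    def test_removed_set_matches_degree_oracle(self):
        rng = random.Random(6)
        genes = [f"g{i}" for i in range(20)]
        pws = [f"p{i}" for i in range(6)]
        edges = pd.DataFrame(
            {
                "source_id": [rng.choice(genes) for _ in range(25)],
                "target_id": [rng.choice(pws) for _ in range(25)],
            }
        )
        nodes = {
            "Gene": pd.DataFrame({"identifier": genes}),
            "Pathway": pd.DataFrame({"identifier": pws}),
        }
        out = prune_disconnected(nodes, [(edges, "Gene", "Pathway")],
                                 {"Gene", "Pathway"})
        assert set(out["Gene"].identifier) == set(edges.source_id)
        assert set(out["Pathway"].identifier) == set(edges.target_id)


class TestAdapterRunner:
    def test_bundled_registry_covers_nineteen_sources(self):
        assert len(bundled_adapter_registry()) == 19

    def test_empty_filter_chain_passes_rows_through(self, corpus_dir):
        registry = bundled_adapter_registry()
        node_tables, _, report = run_adapter(registry["sider"], corpus_dir)
        raw = pd.read_csv(
            corpus_dir / "sider_side_effects.tsv", sep="\t", dtype=str
        )
        assert len(node_tables["side_effect"]) == len(raw)
        assert report["filters"] == []

    def test_filter_report_counts_telescope(self, corpus_dir):
        registry = bundled_adapter_registry()
        _, _, report = run_adapter(registry["ctd"], corpus_dir)
        for entry in report["filters"]:
            assert entry["rows_in"] - entry["removed"] == entry["rows_out"]
        # the two sequential chem_gene filters compose like their product
        chem_gene = [f for f in report["filters"] if f["input"] == "chem_gene"]
        raw = pd.read_csv(corpus_dir / "ctd_chem_gene.tsv", sep="\t", dtype=str,
                          keep_default_na=False)
        survivors = filter_requires_reference(
            filter_by_taxon(raw, "taxon_id"), "pubmed_ids"
        )
        assert chem_gene[-1]["rows_out"] == len(survivors)

    def test_missing_input_is_configuration_error(self, tmp_path):
        from kgforge.errors import ConfigurationError

        registry = bundled_adapter_registry()
        with pytest.raises(ConfigurationError, match="missing"):
            run_adapter(registry["sider"], tmp_path)
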