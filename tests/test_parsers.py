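"""Source-format parsers checked against independent third-party readers."""

import io
import random
import textwrap

import obonet
import pytest
from Bio import SeqIO

from kgforge.errors import FormatError
from kgforge.parsers import (
    parse_fasta,
    parse_gmt,
    parse_obo,
    parse_sdf,
    read_annotation_tsv,
)

OBO_FIXTURE = textwrap.dedent(
    """\
    format-version: 1.2

    [Term]
    id: X:1
    name: root

    [Term]
    id: X:2
    name: child two
    is_a: X:1 ! root
    xref: UMLS:C1
    synonym: "second child" EXACT []

    [Term]
    id: X:3
    name: child three
    is_a: X:1
    relationship: part_of X:2

    [Term]
    id: X:4
    name: grandchild
    is_a: X:2
    is_a: X:3

    [Term]
    id: X:5
    name: gone
    is_obsolete: true
    is_a: X:1

    [Typedef]
    id: part_of
    """
)


class TestParseObo:
    def test_node_rows_and_per_relation_edge_tables(self):
        nodes, edges = parse_obo(io.StringIO(OBO_FIXTURE))
        assert len(nodes) == 5  # one row per [Term], obsolete included
        assert set(edges) == {"is_a", "part_of"}
        assert len(edges["is_a"]) == 4  # obsolete term contributes none
        assert len(edges["part_of"]) == 1

    def test_obsolete_terms_flagged_without_edges(self):
        nodes, edges = parse_obo(io.StringIO(OBO_FIXTURE))
        row = nodes[nodes.identifier == "X:5"].iloc[0]
        assert row.is_obsolete == "true"
        assert "X:5" not in set(edges["is_a"].source_id)

    def test_edge_counts_match_line_grep_oracle(self):
        live_lines = []
        obsolete = False
        for stanza in OBO_FIXTURE.split("[Term]"):
            if "is_obsolete: true" in stanza:
                continue
            live_lines += [
                l for l in stanza.splitlines() if l.startswith("is_a:")
            ]
        _, edges = parse_obo(io.StringIO(OBO_FIXTURE))
        assert len(edges["is_a"]) == len(live_lines)

    def test_agrees_with_obonet(self, tmp_path):
        path = tmp_path / "x.obo"
        path.write_text(OBO_FIXTURE)
        graph = obonet.read_obo(str(path))
        nodes, edges = parse_obo(str(path))
        live = nodes[nodes.is_obsolete == "false"]
        assert set(live.identifier) == set(graph.nodes)
        ours = set(zip(edges["is_a"].source_id, edges["is_a"].target_id))
        theirs = {
            (u, v) for u, v, k in graph.edges(keys=True) if k == "is_a"
        }
        assert ours == theirs

    def test_stanza_without_id_is_format_error(self):
        with pytest.raises(FormatError, match="stanza #0"):
            parse_obo(io.StringIO("[Term]\nname: broken\n"))

    def test_synonym_scopes_kept_in_parallel_column(self):
        nodes, _ = parse_obo(io.StringIO(OBO_FIXTURE))
        row = nodes[nodes.identifier == "X:2"].iloc[0]
        assert row.synonyms == "second child"
        assert row.synonym_scopes == "EXACT"


SDF_FIXTURE = (
    "mol1\n  x\n\nM  END\n> <ID>\nA1\n\n> <SMILES>\nCCO\n\n$$$$\n"
    "mol2\n  x\n\nM  END\n> <ID>\nA2\n\n> <CAS>\n1-2-3\n\n$$$$\n"
)


class TestParseSdf:
    def test_union_of_keys_forms_header(self):
        table = parse_sdf(io.StringIO(SDF_FIXTURE))
        assert list(table.columns) == ["ID", "SMILES", "CAS", "structure"]
        assert len(table) == 2
        assert table.loc[0, "CAS"] == ""  # absent key -> empty cell
        assert table.loc[1, "CAS"] == "1-2-3"

    def test_empty_stream_yields_empty_table(self):
        assert parse_sdf(io.StringIO("")).empty

    def test_cells_match_independent_stanza_splitter(self):
        table = parse_sdf(io.StringIO(SDF_FIXTURE))
        chunks = [c for c in SDF_FIXTURE.split("$$$$\n") if c.strip()]
        assert len(table) == len(chunks)
        for pos, chunk in enumerate(chunks):
            for line, next_line in zip(chunk.splitlines(), chunk.splitlines()[1:]):
                if line.startswith("> <"):
                    key = line[3:-1]
                    assert table.loc[pos, key] == next_line

    def test_truncated_record_is_format_error(self):
        with pytest.raises(FormatError, match="truncated"):
            parse_sdf(io.StringIO("mol\nM  END\n> <ID>\nA\n"))

    def test_structure_block_preserved_verbatim(self):
        table = parse_sdf(io.StringIO(SDF_FIXTURE))
        assert table.loc[0, "structure"].startswith("mol1")
        assert "M  END" in table.loc[0, "structure"]


class TestParseFasta:
    def test_multiline_sequences_concatenated(self):
        records = parse_fasta(io.StringIO(">a desc\nACGT\nACGT\n>b\nTTTT\n"))
        assert [(r.header, r.sequence) for r in records] == [
            ("a desc", "ACGTACGT"), ("b", "TTTT"),
        ]

    def test_sequence_before_header_is_format_error(self):
        with pytest.raises(FormatError):
            parse_fasta(io.StringIO("ACGT\n>late\nAA\n"))

    def test_random_line_wrapping_recovers_originals(self):
        rng = random.Random(17)
        originals = {
            f"seq{i}": "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(60))
            for i in range(8)
        }
        lines = []
        for header, seq in originals.items():
            lines.append(f">{header}")
            pos = 0
            while pos < len(seq):
                width = rng.randrange(5, 30)
                lines.append(seq[pos:pos + width])
                pos += width
        records = parse_fasta(io.StringIO("\n".join(lines)))
        assert {r.header: r.sequence for r in records} == originals

    def test_agrees_with_biopython(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">p1 protein one\nMKV\nLLA\n>p2\nGGG\n")
        ours = parse_fasta(str(path))
        theirs = list(SeqIO.parse(str(path), "fasta"))
        assert [r.sequence for r in ours] == [str(r.seq) for r in theirs]
        assert [r.header.split()[0] for r in ours] == [r.id for r in theirs]


class TestParseGmt:
    def test_members_deduplicated_order_preserved(self):
        entries = parse_gmt(io.StringIO("pw1\tdesc\tG1\tG2\tG1\n"))
        assert entries[0].members == ["G1", "G2"]

    def test_empty_stream_yields_no_entries(self):
        assert parse_gmt(io.StringIO("")) == []

    def test_short_line_is_format_error_with_line_number(self):
        with pytest.raises(FormatError, match="line 2"):
            parse_gmt(io.StringIO("ok\tdesc\tG1\nbroken\n"))

    def test_member_sets_match_field_split_oracle(self):
        rng = random.Random(23)
        lines = []
        for i in range(10):
            members = [f"G{rng.randrange(8)}" for _ in range(rng.randrange(1, 12))]
            lines.append("\t".join([f"set{i}", "d"] + members))
        entries = parse_gmt(io.StringIO("\n".join(lines)))
        assert len(entries) == 10
        for line, entry in zip(lines, entries):
            fields = line.split("\t")[2:]
            assert entry.members == list(dict.fromkeys(fields))


class TestAnnotationTsv:
    def test_comment_lines_skipped(self):
        table = read_annotation_tsv(
            io.StringIO("!gaf-version: 2.2\n!date: x\na\tb\n1\t2\n"),
        )
        assert list(table.columns) == ["a", "b"]
        assert len(table) == 1

    def test_headerless_mode_uses_given_columns(self):
        table = read_annotation_tsv(
            io.StringIO("!x\nP1\tGO:1\n"), column_names=["protein", "go"]
        )
        assert table.loc[0, "go"] == "GO:1"
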