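"""Parsers converting heterogeneous source formats into normalized tables.

Covered formats: OBO flat files (term-centric node table plus one edge
table per relation), SDF V2000 records ("$$$$"-terminated key-value
objects), FASTA header/sequence pairs, GMT gene sets, and GAF-style
annotation TSVs with "!" comment lines.

The OBO converter emits one node row per ``[Term]`` stanza and one edge
table per distinct relation name (``is_a`` plus each ``relationship:``
tag).  ``[Typedef]`` stanzas only populate a relation-name registry.
Obsolete terms are flagged and contribute no edge rows.  ``alt_id`` tags
are folded into the xref list column.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError


def _lines(stream) -> list[str]:
    if isinstance(stream, (str, Path)):
        text = Path(stream).read_text(encoding="utf-8")
    elif isinstance(stream, bytes):
        text = stream.decode("utf-8")
    elif hasattr(stream, "read"):
        text = stream.read()
        if isinstance(text, bytes):
            text = text.decode("utf-8")
    else:
        text = str(stream)
    return text.splitlines()


# ----------------------------------------------------------------------- OBO


@dataclass
class OboTerm:
    """One [Term] stanza of an OBO ontology."""

    term_id: str
    name: str = ""
    definition: str | None = None
    synonyms: list[str] = field(default_factory=list)
    synonym_scopes: list[str] = field(default_factory=list)
    xrefs: list[str] = field(default_factory=list)
    relations: list[tuple[str, str]] = field(default_factory=list)
    is_obsolete: bool = False
    namespace: str = ""


def _strip_obo_comment(value: str) -> str:
    return value.split(" ! ", 1)[0].strip()


def _parse_quoted(value: str) -> tuple[str, str]:
    """Split a quoted OBO value into (text, trailer)."""
    if not value.startswith('"'):
        return value, ""
    end = value.find('"', 1)
    while end != -1 and value[end - 1] == "\\":
        end = value.find('"', end + 1)
    if end == -1:
        return value.strip('"'), ""
    return value[1:end].replace('\\"', '"'), value[end + 1:].strip()


def iter_obo_stanzas(stream) -> tuple[list[OboTerm], list[str]]:
    """All [Term] stanzas plus the relation names declared by [Typedef]s."""
    terms: list[OboTerm] = []
    typedefs: list[str] = []
    stanza_type: str | None = None
    tags: list[tuple[str, str]] = []
    stanza_index = 0

    def flush():
        nonlocal tags, stanza_type, stanza_index
        if stanza_type == "Term":
            terms.append(_term_from_tags(tags, stanza_index))
        elif stanza_type == "Typedef":
            for tag, value in tags:
                if tag == "id":
                    typedefs.append(_strip_obo_comment(value))
        if stanza_type is not None:
            stanza_index += 1
        tags = []

    for raw in _lines(stream):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            stanza_type = line[1:-1]
            continue
        if stanza_type is None:
            continue  # header clauses (format-version etc.)
        if ":" not in line:
            continue
        tag, value = line.split(":", 1)
        tags.append((tag.strip(), value.strip()))
    flush()
    return terms, typedefs


def _term_from_tags(tags: list[tuple[str, str]], stanza_index: int) -> OboTerm:
    term_id = None
    for tag, value in tags:
        if tag == "id":
            term_id = _strip_obo_comment(value)
            break
    if not term_id:
        raise FormatError(f"[Term] stanza #{stanza_index} has no id tag")
    term = OboTerm(term_id=term_id)
    for tag, value in tags:
        if tag == "name":
            term.name = value
        elif tag == "def":
            term.definition = _parse_quoted(value)[0]
        elif tag == "synonym":
            text, trailer = _parse_quoted(value)
            term.synonyms.append(text)
            scope = trailer.split(" ", 1)[0].strip("[]") if trailer else ""
            term.synonym_scopes.append(scope or "RELATED")
        elif tag in ("xref", "alt_id"):
            term.xrefs.append(_strip_obo_comment(value))
        elif tag == "is_a":
            term.relations.append(("is_a", _strip_obo_comment(value)))
        elif tag == "relationship":
            parts = _strip_obo_comment(value).split()
            if len(parts) >= 2:
                term.relations.append((parts[0], parts[1]))
        elif tag == "is_obsolete":
            term.is_obsolete = value.strip().lower() == "true"
        elif tag == "namespace":
            term.namespace = value.strip()
    return term


def parse_obo(stream, delimiter: str = "|") -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """OBO stream -> (node table, relation name -> edge table).

    The node table has one row per [Term] stanza with list-valued cells
    joined on ``delimiter``; each edge table has source_id/target_id
    columns.  Obsolete terms are flagged in the node table and emit no
    edge rows.
    """
    terms, typedefs = iter_obo_stanzas(stream)
    rows = []
    edges: dict[str, list[tuple[str, str]]] = {}
    for name in typedefs:
        edges.setdefault(name, [])
    for term in terms:
        rows.append(
            {
                "identifier": term.term_id,
                "name": term.name,
                "definition": term.definition or "",
                "synonyms": delimiter.join(term.synonyms),
                "synonym_scopes": delimiter.join(term.synonym_scopes),
                "xrefs": delimiter.join(term.xrefs),
                "namespace": term.namespace,
                "is_obsolete": "true" if term.is_obsolete else "false",
            }
        )
        if term.is_obsolete:
            continue
        for relation, target in term.relations:
            edges.setdefault(relation, []).append((term.term_id, target))
    node_table = pd.DataFrame(
        rows,
        columns=[
            "identifier", "name", "definition", "synonyms",
            "synonym_scopes", "xrefs", "namespace", "is_obsolete",
        ],
    )
    edge_tables = {
        relation: pd.DataFrame(pairs, columns=["source_id", "target_id"])
        for relation, pairs in edges.items()
        if pairs
    }
    return node_table, edge_tables


# ----------------------------------------------------------------------- SDF


@dataclass
class SdfRecord:
    title: str
    structure_block: str
    properties: dict[str, str]


def iter_sdf_records(stream) -> list[SdfRecord]:
    lines = _lines(stream)
    records: list[SdfRecord] = []
    buffer: list[str] = []
    for line in lines:
        if line.strip() == "$$$$":
            records.append(_sdf_record(buffer))
            buffer = []
        else:
            buffer.append(line)
    if any(l.strip() for l in buffer):
        raise FormatError("truncated SDF record: EOF before '$$$$' terminator")
    return records


def _sdf_record(lines: list[str]) -> SdfRecord:
    structure: list[str] = []
    properties: dict[str, str] = {}
    i = 0
    while i < len(lines) and not lines[i].startswith(">"):
        structure.append(lines[i])
        i += 1
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            i += 1
            continue
        key = header[header.find("<") + 1 : header.rfind(">")]
        i += 1
        values: list[str] = []
        while i < len(lines) and lines[i].strip() != "":
            values.append(lines[i])
            i += 1
        if key in properties:
            raise FormatError(f"duplicate SDF property key {key!r}")
        properties[key] = "\n".join(values)
        i += 1
    title = structure[0].strip() if structure else ""
    return SdfRecord(title=title, structure_block="\n".join(structure), properties=properties)


def parse_sdf(stream) -> pd.DataFrame:
    """SDF stream -> one row per record; property-key union forms the header.

    Absent keys become empty cells; the raw structure block is preserved in
    a dedicated ``structure`` column so fingerprinting can consume either
    the block or a SMILES property downstream.
    """
    records = iter_sdf_records(stream)
    columns: list[str] = []
    for record in records:
        for key in record.properties:
            if key not in columns:
                columns.append(key)
    rows = [
        {**{c: r.properties.get(c, "") for c in columns}, "structure": r.structure_block}
        for r in records
    ]
    return pd.DataFrame(rows, columns=columns + ["structure"] if records else [])


# --------------------------------------------------------------------- FASTA


@dataclass
class FastaRecord:
    header: str
    sequence: str


def parse_fasta(stream) -> list[FastaRecord]:
    """FASTA stream -> records with multi-line sequences concatenated."""
    records: list[FastaRecord] = []
    header: str | None = None
    chunks: list[str] = []
    for line in _lines(stream):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                records.append(FastaRecord(header, "".join(chunks)))
            header = line[1:]
            chunks = []
        else:
            if header is None:
                raise FormatError("sequence data before any FASTA header")
            chunks.append(line)
    if header is not None:
        records.append(FastaRecord(header, "".join(chunks)))
    return records


# ----------------------------------------------------------------------- GMT


@dataclass
class GmtEntry:
    set_name: str
    description: str
    members: list[str]


def parse_gmt(stream) -> list[GmtEntry]:
    """GMT stream -> entries with members deduplicated, order preserved."""
    entries: list[GmtEntry] = []
    for number, line in enumerate(_lines(stream), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"GMT line {number} has fewer than 2 tab-separated fields")
        members = list(dict.fromkeys(f for f in fields[2:] if f != ""))
        entries.append(GmtEntry(fields[0], fields[1], members))
    return entries


# ----------------------------------------------------------------- GAF / TSV


def read_annotation_tsv(
    stream,
    column_names: list[str] | None = None,
    comment_prefix: str = "!",
) -> pd.DataFrame:
    """GAF-style annotation TSV: skip comment lines, then plain TSV.

    With ``column_names`` the file is treated as headerless (the GAF
    convention); otherwise the first non-comment row is the header.
    """
    text = "\n".join(
        line for line in _lines(stream) if not line.startswith(comment_prefix)
    )
    if not text.strip():
        return pd.DataFrame(columns=column_names or [])
    return pd.read_csv(
        io.StringIO(text),
        sep="\t",
        dtype=str,
        keep_default_na=False,
        header=None if column_names else 0,
        names=column_names,
    )
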