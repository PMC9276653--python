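"""Per-source preparation: quality filters, deduplication, adapter runner.

The filter catalogue collects the per-source quality rules applied during
data preparation: human-taxon gene filtering (NCBI taxonomy id 9606),
direct-evidence requirements on chemical/gene-disease associations,
adverse-event signal thresholds (report frequency >= 0.1% and at least
100 reports), clinical-annotation evidence levels {1,2,3} and "yes"
significance flags, PubMed-reference requirements, pathway-source
whitelists, experimental-evidence interaction filters, and semi-joins
against current identifier lists.

Every rule is a pure, deterministic function of its parameters; rules are
idempotent and preserve row order.  :func:`run_adapter` applies a
configured chain of rules to parsed inputs and emits node/edge tables
plus a run report with per-filter row counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError
from . import parsers

logger = logging.getLogger(__name__)

#: Paper-default thresholds for the adverse-event outcome filter.
DEFAULT_MIN_FREQUENCY_PERCENT = 0.1
DEFAULT_MIN_REPORT_COUNT = 100
#: Accepted clinical-annotation evidence levels and significance flag.
DEFAULT_EVIDENCE_LEVELS = frozenset({"1", "2", "3"})
DEFAULT_SIGNIFICANCE = "yes"
#: NCBI taxonomy id for Homo sapiens.
HUMAN_TAXON_ID = 9606
#: Pathway providers whose licensing permits redistribution.
DEFAULT_PATHWAY_WHITELIST = frozenset(
    {"WikiPathways", "Reactome", "Panther", "NetPath", "PathBank"}
)

LIST_DELIMITER = "|"


# ------------------------------------------------------------------- filters


def filter_by_taxon(
    rows: pd.DataFrame, taxon_column: str, taxon_id: int = HUMAN_TAXON_ID
) -> pd.DataFrame:
    """Keep only rows whose taxon equals ``taxon_id``; non-integer cells are
    rejected and logged."""
    if taxon_column not in rows.columns:
        raise FormatError(f"taxon column {taxon_column!r} missing")

    def keep(value: str) -> bool:
        try:
            return int(str(value).strip()) == taxon_id
        except ValueError:
            logger.warning("rejecting row with non-integer taxon %r", value)
            return False

    return rows[rows[taxon_column].map(keep)].reset_index(drop=True)


def filter_direct_evidence(rows: pd.DataFrame, evidence_column: str) -> pd.DataFrame:
    """Drop rows whose evidence cell is empty or whitespace-only."""
    if evidence_column not in rows.columns:
        raise FormatError(f"evidence column {evidence_column!r} missing")
    mask = rows[evidence_column].map(lambda v: str(v).strip() != "")
    return rows[mask].reset_index(drop=True)


def filter_outcome_pairs(
    pairs: pd.DataFrame,
    frequency_column: str = "frequency",
    count_column: str = "report_count",
    min_frequency_percent: float = DEFAULT_MIN_FREQUENCY_PERCENT,
    min_count: int = DEFAULT_MIN_REPORT_COUNT,
) -> pd.DataFrame:
    """Adverse-event signal filter: a drug-outcome pair survives iff its
    report frequency (in percent) is at least ``min_frequency_percent`` AND
    its report count is at least ``min_count`` (inclusive bounds).

    Negative values are rejected and logged.
    """
    for col in (frequency_column, count_column):
        if col not in pairs.columns:
            raise FormatError(f"column {col!r} missing from outcome pairs")

    def keep(row) -> bool:
        freq = float(row[frequency_column])
        count = float(row[count_column])
        if freq < 0 or count < 0:
            logger.warning("rejecting outcome pair with negative values: %s", dict(row))
            return False
        return freq >= min_frequency_percent and count >= min_count

    mask = pairs.apply(keep, axis=1) if len(pairs) else pd.Series([], dtype=bool)
    return pairs[mask].reset_index(drop=True)


def filter_annotation_evidence(
    rows: pd.DataFrame,
    level_column: str = "evidence_level",
    significance_column: str = "significance",
    levels: frozenset[str] = DEFAULT_EVIDENCE_LEVELS,
    significance: str = DEFAULT_SIGNIFICANCE,
) -> pd.DataFrame:
    """Clinical rows survive iff their evidence level is 1, 2 or 3; variant
    annotation rows survive iff their significance flag equals "yes".

    Rows state at most one of the two fields; a populated level marks a
    clinical annotation, a populated significance flag a variant
    annotation.  Unparseable levels are rejected and logged.
    """
    for col in (level_column, significance_column):
        if col not in rows.columns:
            raise FormatError(f"column {col!r} missing from annotations")

    def keep(row) -> bool:
        level = str(row[level_column]).strip()
        sig = str(row[significance_column]).strip()
        if level:
            try:
                normalized = str(int(float(level)))
            except ValueError:
                logger.warning("rejecting annotation with unparseable level %r", level)
                return False
            if normalized not in levels:
                return False
        if sig and sig.lower() != significance:
            return False
        return True

    mask = rows.apply(keep, axis=1) if len(rows) else pd.Series([], dtype=bool)
    return rows[mask].reset_index(drop=True)


def filter_requires_reference(
    rows: pd.DataFrame, reference_column: str, delimiter: str = LIST_DELIMITER
) -> pd.DataFrame:
    """Keep only rows whose reference list cell is non-empty."""
    if reference_column not in rows.columns:
        raise FormatError(f"reference column {reference_column!r} missing")
    mask = rows[reference_column].map(
        lambda v: any(p.strip() for p in str(v).split(delimiter))
    )
    return rows[mask].reset_index(drop=True)


def filter_source_whitelist(
    rows: pd.DataFrame,
    source_column: str,
    allowed: frozenset[str] = DEFAULT_PATHWAY_WHITELIST,
) -> pd.DataFrame:
    """Keep rows whose source column value is in the whitelist."""
    if source_column not in rows.columns:
        raise FormatError(f"source column {source_column!r} missing")
    allowed = frozenset(allowed)
    mask = rows[source_column].map(lambda v: str(v) in allowed)
    return rows[mask].reset_index(drop=True)


def filter_evidence_contains(
    rows: pd.DataFrame, evidence_column: str, token: str = "exp",
    delimiter: str = LIST_DELIMITER,
) -> pd.DataFrame:
    """Keep rows whose evidence-type list contains ``token`` (the
    experimental-evidence requirement on protein interactions)."""
    if evidence_column not in rows.columns:
        raise FormatError(f"evidence column {evidence_column!r} missing")
    mask = rows[evidence_column].map(
        lambda v: token in [p.strip() for p in str(v).split(delimiter)]
    )
    return rows[mask].reset_index(drop=True)


def filter_in_identifier_list(
    rows: pd.DataFrame, id_column: str, identifiers
) -> pd.DataFrame:
    """Semi-join against a current identifier list (UniProt reconciliation,
    dbSNP rs-id pruning)."""
    if id_column not in rows.columns:
        raise FormatError(f"identifier column {id_column!r} missing")
    identifiers = frozenset(str(i) for i in identifiers)
    mask = rows[id_column].map(lambda v: str(v) in identifiers)
    return rows[mask].reset_index(drop=True)


# ------------------------------------------------------- evidence-code table


def _load_evidence_table() -> dict[str, str]:
    path = resources.files("kgforge").joinpath("data/evidence_codes.tsv")
    table = pd.read_csv(str(path), sep="\t", dtype=str)
    return dict(zip(table["code"], table["description"]))


EVIDENCE_CODES: dict[str, str] = _load_evidence_table()


def translate_evidence_code(code: str, table: dict[str, str] | None = None) -> str:
    """Annotation evidence abbreviation -> descriptive text; unknown codes
    pass through unchanged with a warning."""
    table = EVIDENCE_CODES if table is None else table
    if code not in table:
        logger.warning("unknown evidence code %r passed through", code)
        return code
    return table[code]


# ------------------------------------------------------------------- dedupe


def dedupe_entities(
    rows: pd.DataFrame, key_columns: list[str], delimiter: str = LIST_DELIMITER
) -> pd.DataFrame:
    """First occurrence per key wins; list-valued non-key columns are
    unioned across duplicates (order of first appearance)."""
    for col in key_columns:
        if col not in rows.columns:
            raise FormatError(f"key column {col!r} missing")
    list_columns = {
        col
        for col in rows.columns
        if col not in key_columns
        and rows[col].map(lambda v: delimiter in str(v)).any()
    }
    out_rows: dict[tuple, dict] = {}
    for _, row in rows.iterrows():
        key = tuple(row[c] for c in key_columns)
        if key not in out_rows:
            out_rows[key] = dict(row)
            continue
        kept = out_rows[key]
        for col in list_columns:
            old = [p for p in str(kept[col]).split(delimiter) if p != ""]
            new = [p for p in str(row[col]).split(delimiter) if p != ""]
            kept[col] = delimiter.join(old + [p for p in new if p not in old])
    return pd.DataFrame(list(out_rows.values()), columns=list(rows.columns))


# -------------------------------------------------------- prune_disconnected


def prune_disconnected(
    node_tables: dict[str, pd.DataFrame],
    edge_tables: list[tuple[pd.DataFrame, str, str]],
    prune_labels: set[str],
    keep_labels: set[str] = frozenset(),
) -> dict[str, pd.DataFrame]:
    """Remove nodes of ``prune_labels`` with zero incident edge rows.

    ``edge_tables`` items are (table, source label, target label) with
    source_id/target_id columns.  Labels in ``keep_labels`` are never
    pruned (disjoint chemicals stay available for later mapping).
    """
    touched: dict[str, set[str]] = {label: set() for label in node_tables}
    for table, src_label, dst_label in edge_tables:
        if src_label in touched and "source_id" in table.columns:
            touched[src_label].update(table["source_id"].astype(str))
        if dst_label in touched and "target_id" in table.columns:
            touched[dst_label].update(table["target_id"].astype(str))
    out: dict[str, pd.DataFrame] = {}
    for label, table in node_tables.items():
        if label in prune_labels and label not in keep_labels:
            mask = table["identifier"].map(lambda v: str(v) in touched[label])
            out[label] = table[mask].reset_index(drop=True)
        else:
            out[label] = table.reset_index(drop=True)
    return out


# ----------------------------------------------------------- adapter runner

#: rule id -> callable; parameters are passed as keyword arguments.
FILTER_CATALOGUE = {
    "taxon": filter_by_taxon,
    "direct_evidence": filter_direct_evidence,
    "outcome_pairs": filter_outcome_pairs,
    "annotation_evidence": filter_annotation_evidence,
    "requires_reference": filter_requires_reference,
    "source_whitelist": filter_source_whitelist,
    "evidence_contains": filter_evidence_contains,
    "in_identifier_list": filter_in_identifier_list,
    "dedupe": dedupe_entities,
}


@dataclass
class FilterRule:
    """A catalogue rule bound to parameters; pure and deterministic."""

    rule_id: str
    parameters: dict = field(default_factory=dict)
    input: str = "main"

    def apply(self, rows: pd.DataFrame) -> pd.DataFrame:
        try:
            fn = FILTER_CATALOGUE[self.rule_id]
        except KeyError:
            raise ConfigurationError(f"unknown filter rule {self.rule_id!r}") from None
        return fn(rows, **self.parameters)


@dataclass
class AdapterSpec:
    """Declarative description of one source-preparation stage."""

    source_name: str
    inputs: dict[str, dict]  # logical name -> {path, format, options}
    filters: list[FilterRule] = field(default_factory=list)
    emitters: list[dict] = field(default_factory=list)

    @staticmethod
    def from_dict(config: dict) -> "AdapterSpec":
        filters = [
            FilterRule(
                rule_id=f["rule"],
                parameters=dict(f.get("params", {})),
                input=f.get("input", "main"),
            )
            for f in config.get("filters", [])
        ]
        for rule in filters:
            if rule.rule_id not in FILTER_CATALOGUE:
                raise ConfigurationError(
                    f"adapter {config.get('source')!r} names unknown rule {rule.rule_id!r}"
                )
        return AdapterSpec(
            source_name=config["source"],
            inputs=dict(config.get("inputs", {})),
            filters=filters,
            emitters=list(config.get("emitters", [])),
        )


def _load_input(path: Path, fmt: str, options: dict) -> object:
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if fmt == "gaf":
        return parsers.read_annotation_tsv(path, column_names=options.get("columns"))
    if fmt == "obo":
        nodes, edges = parsers.parse_obo(path)
        return {"nodes": nodes, "edges": edges}
    if fmt == "sdf":
        return parsers.parse_sdf(path)
    if fmt == "fasta":
        return parsers.parse_fasta(path)
    if fmt == "gmt":
        return parsers.parse_gmt(path)
    if fmt == "graphml":
        from . import graphml

        return graphml.read_graphml(path)
    raise ConfigurationError(f"unknown input format {fmt!r}")


def _resolve_table(loaded: object, selector: str | None) -> pd.DataFrame:
    if isinstance(loaded, pd.DataFrame):
        return loaded
    if isinstance(loaded, dict):
        if selector == "nodes" or selector is None:
            return loaded["nodes"]
        if selector.startswith("edges:"):
            return loaded["edges"].get(
                selector.split(":", 1)[1], pd.DataFrame(columns=["source_id", "target_id"])
            )
    if isinstance(loaded, list) and loaded and isinstance(loaded[0], parsers.GmtEntry):
        return pd.DataFrame(
            {
                "identifier": [e.set_name for e in loaded],
                "description": [e.description for e in loaded],
                "members": [LIST_DELIMITER.join(e.members) for e in loaded],
            }
        )
    raise ConfigurationError(f"cannot derive a table from input (selector={selector!r})")


def run_adapter(
    spec: AdapterSpec, base_dir: Path | str
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], dict]:
    """Apply the filter chain and emitters of one adapter.

    Returns (node tables keyed by label, edge tables keyed by type name,
    run report).  The report records per-filter input/output row counts;
    counts telescope: input rows minus removed rows equals output rows.
    """
    base_dir = Path(base_dir)
    loaded: dict[str, object] = {}
    for logical, binding in spec.inputs.items():
        path = base_dir / binding["path"]
        if not path.exists():
            raise ConfigurationError(
                f"adapter {spec.source_name!r}: input {logical!r} missing at {path}"
            )
        loaded[logical] = _load_input(path, binding.get("format", "tsv"), binding)

    tables: dict[str, pd.DataFrame] = {}
    for logical, obj in loaded.items():
        if isinstance(obj, pd.DataFrame):
            tables[logical] = obj
        elif isinstance(obj, dict):  # parsed OBO
            tables[logical] = obj["nodes"]
            for rel, edge_table in obj["edges"].items():
                tables[f"{logical}:edges:{rel}"] = edge_table
        elif isinstance(obj, list) and (not obj or isinstance(obj[0], parsers.GmtEntry)):
            tables[logical] = _resolve_table(obj, None)

    report: dict = {"source": spec.source_name, "filters": []}
    for rule in spec.filters:
        if rule.input not in tables:
            raise ConfigurationError(
                f"adapter {spec.source_name!r}: filter {rule.rule_id!r} targets "
                f"unknown input {rule.input!r}"
            )
        before = len(tables[rule.input])
        tables[rule.input] = rule.apply(tables[rule.input])
        after = len(tables[rule.input])
        report["filters"].append(
            {"rule": rule.rule_id, "input": rule.input,
             "rows_in": before, "rows_out": after, "removed": before - after}
        )

    node_tables: dict[str, pd.DataFrame] = {}
    edge_tables: dict[str, pd.DataFrame] = {}
    for emitter in spec.emitters:
        table = tables[emitter.get("input", "main")]
        columns = emitter.get("columns")
        if columns:
            table = table.rename(columns=columns)[list(columns.values())]
        if emitter["kind"] == "nodes":
            node_tables[emitter["label"]] = table.reset_index(drop=True)
        elif emitter["kind"] == "edges":
            edge_tables[emitter["type_name"]] = table.reset_index(drop=True)
        else:
            raise ConfigurationError(f"unknown emitter kind {emitter['kind']!r}")
    report["nodes"] = {label: len(t) for label, t in node_tables.items()}
    report["edges"] = {name: len(t) for name, t in edge_tables.items()}
    return node_tables, edge_tables, report


def load_adapter_registry(config_dir: Path | str) -> dict[str, AdapterSpec]:
    """Load every ``*.yaml`` adapter config in a directory into a registry
    keyed by source name; duplicate source names are rejected."""
    registry: dict[str, AdapterSpec] = {}
    for path in sorted(Path(config_dir).glob("*.yaml")):
        spec = AdapterSpec.from_dict(yaml.safe_load(path.read_text()))
        if spec.source_name in registry:
            raise ConfigurationError(f"duplicate adapter source {spec.source_name!r}")
        registry[spec.source_name] = spec
    return registry


def bundled_adapter_registry() -> dict[str, AdapterSpec]:
    """Registry of the bundled per-source adapter configs."""
    config_dir = resources.files("kgforge").joinpath("configs/sources")
    return load_adapter_registry(str(config_dir))
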