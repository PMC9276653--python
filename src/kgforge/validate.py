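"""Technical-validation checks and final merged-subgraph extraction.

Validators return reports rather than raising, so callers can emit
machine-readable JSON and decide the exit code themselves.  A graph
passes a check iff its report lists no violations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import GraphStore
from .naming import AbbreviationRegistry, DEFAULT_REGISTRY, parse_edge_type

#: Abbreviation aliases accepted by the edge-name validator.  The published
#: schema uses "P" for Phenotype in one OMIM edge type although Phenotype
#: abbreviates to PT elsewhere; the alias keeps that printed type valid.
ABBREV_ALIASES: dict[str, frozenset[str]] = {"P": frozenset({"Protein", "Phenotype"})}

#: Labels whose data must be human-only.
HUMAN_ONLY_LABELS = frozenset(
    {"Gene", "Protein", "Pathway", "Variant", "SideEffect", "Symptom", "Phenotype"}
)
HUMAN_TAXON_ID = 9606


@dataclass
class ValidationReport:
    """Violations plus per-rule checked counts; empty violations == pass."""

    rule_id: str
    violations: list[tuple[str, str, str]] = field(default_factory=list)
    checked: int = 0

    @property
    def passed(self) -> bool:
        return not self.violations

    def add(self, entity_id: str, message: str) -> None:
        self.violations.append((entity_id, self.rule_id, message))

    def to_dict(self) -> dict:
        return {
            "rule": self.rule_id,
            "checked": self.checked,
            "violations": [
                {"entity": e, "rule": r, "message": m} for e, r, m in self.violations
            ],
        }


def _abbrev_matches(abbrev: str, labels: tuple[str, ...], registry) -> bool:
    allowed = ABBREV_ALIASES.get(abbrev)
    if allowed is not None and allowed & set(labels):
        return True
    return registry.has_abbrev(abbrev) and registry.label_for(abbrev) in labels


def validate_edge_names(
    store: GraphStore, registry: AbbreviationRegistry = DEFAULT_REGISTRY
) -> ValidationReport:
    """Every edge type must parse under the naming grammar and its
    abbreviations must abbreviate labels of the incident nodes."""
    report = ValidationReport("edge_names")
    for edge_id in sorted(store.edges):
        edge = store.edges[edge_id]
        report.checked += 1
        parsed = parse_edge_type(edge.type_name, registry)
        if not parsed:
            report.add(edge_id, f"{edge.type_name!r}: {parsed.reason}")
            continue
        src_labels = store.nodes[edge.source_id].labels
        dst_labels = store.nodes[edge.target_id].labels
        if not _abbrev_matches(parsed.src_abbrev, src_labels, registry):
            report.add(
                edge_id,
                f"{edge.type_name!r}: source abbreviation {parsed.src_abbrev!r} "
                f"does not abbreviate any of {list(src_labels)}",
            )
        elif not _abbrev_matches(parsed.dst_abbrev, dst_labels, registry):
            report.add(
                edge_id,
                f"{edge.type_name!r}: target abbreviation {parsed.dst_abbrev!r} "
                f"does not abbreviate any of {list(dst_labels)}",
            )
    return report


def _resource_tagged(properties: dict, source: str) -> bool:
    prefix = source.lower()
    return any(name.startswith(prefix + "_") for name in properties)


def validate_resource_tags(store: GraphStore) -> ValidationReport:
    """Every source named in an entity's resource list must have a
    corresponding source-prefixed tag property on that entity."""
    report = ValidationReport("resource_tags")
    entities = [(nid, n.properties) for nid, n in sorted(store.nodes.items())]
    entities += [(eid, e.properties) for eid, e in sorted(store.edges.items())]
    for entity_id, properties in entities:
        report.checked += 1
        resource = properties.get("resource")
        if not resource:
            continue
        sources = resource if isinstance(resource, list) else [resource]
        for source in sources:
            if not _resource_tagged(properties, str(source)):
                report.add(entity_id, f"resource {source!r} has no tag property")
    return report


def check_human_only(
    store: GraphStore,
    labels: frozenset[str] = HUMAN_ONLY_LABELS,
    taxon_property: str = "taxon_id",
    human_taxon: int = HUMAN_TAXON_ID,
) -> ValidationReport:
    """Nodes of the listed labels whose taxon property exists must carry
    the human taxonomy id."""
    report = ValidationReport("human_only")
    seen: set[str] = set()
    for label in sorted(labels):
        for node in store.nodes_with_label(label):
            if node.node_id in seen:
                continue
            seen.add(node.node_id)
            report.checked += 1
            taxon = node.properties.get(taxon_property)
            if taxon is None:
                continue
            try:
                value = int(str(taxon))
            except ValueError:
                report.add(node.node_id, f"unparseable taxon {taxon!r}")
                continue
            if value != human_taxon:
                report.add(node.node_id, f"non-human taxon {value}")
    return report


@dataclass(frozen=True)
class ExtractionManifest:
    """What the final export keeps: merged-schema entities only, plus the
    index definitions that survive extraction."""

    source_marker: str = "source"


def extract_merged_subgraph(
    store: GraphStore, manifest: ExtractionManifest = ExtractionManifest()
) -> GraphStore:
    """Copy of the graph containing exactly the entities without a
    source-subgraph marker property; no dangling edges; input untouched."""
    out = GraphStore()
    kept: set[str] = set()
    for node_id in sorted(store.nodes):
        node = store.nodes[node_id]
        if manifest.source_marker in node.properties:
            continue
        out.add_node(node.labels, dict(node.properties), node_id=node_id)
        kept.add(node_id)
    for edge_id in sorted(store.edges):
        edge = store.edges[edge_id]
        if manifest.source_marker in edge.properties:
            continue
        if edge.source_id in kept and edge.target_id in kept:
            out.add_edge(
                edge.type_name, edge.source_id, edge.target_id,
                dict(edge.properties), edge_id=edge_id,
            )
    for label, prop in store.index_definitions():
        if label in out.labels():
            out.create_index(label, prop)
    return out


def extract_indices(store: GraphStore) -> list[tuple[str, str]]:
    """Index definitions whose label is live in the (extracted) graph."""
    live = set(store.labels())
    return [(label, prop) for label, prop in store.index_definitions() if label in live]
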