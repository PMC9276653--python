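"""Merge resolved source subgraphs into the unified hetnet schema.

The operations here implement the schema-level merge vocabulary: edge
renames exposing broader labels, node replacement that preserves incident
edges (surrogate ids survive property replacement), match-or-create edge
merging with provenance-aware property union, reified edge-nodes
(Interaction, Treatment, ClinicalAnnotation, VariantAnnotation), label
hierarchies and grouping labels, and the closing EQUAL / allele edge
generation over shared UMLS identifiers, names and rs-identifiers.

Property conflicts on update keep the existing value and store the
incoming one under ``<name>_<source>``; both values stay queryable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ContractError, ForgeError
from .graph import GraphStore, PropertyNode
from .naming import AbbreviationRegistry, DEFAULT_REGISTRY, parse_edge_type
from .resolver import normalize_name

logger = logging.getLogger(__name__)

LIST_DELIMITER = "|"

#: Hetionet compound edge types renamed to expose the Chemical label.
DEFAULT_RENAMES = {
    "CAUSES_CcSE": "CAUSES_CHcSE",
    "PALLIATES_CpD": "PALLIATES_CHpD",
    "TREATS_CtD": "TREATS_CHtD",
    "BINDS_CbG": "BINDS_CHbG",
    "DOWNREGULATES_CdG": "DOWNREGULATES_CHdG",
}

#: Reactome event labels grouped under ReactionLikeEvent.
REACTION_LIKE_LABELS = (
    "Reaction", "FailedReaction", "BlackBoxEvent", "Polymerisation", "Depolymerisation",
)


@dataclass(frozen=True)
class LabelHierarchy:
    """Subsumption pairs plus grouping assignments, applied as a closure.

    ``parents`` maps a label to the labels every node carrying it must
    also carry; the closure over the map is applied, so a Salt node ends
    up with Salt, Compound and Chemical.
    """

    parents: dict = field(
        default_factory=lambda: {
            "Salt": ("Compound",),
            "Compound": ("Chemical",),
            "Disease": ("Phenotype",),
            "Symptom": ("Phenotype",),
            "SideEffect": ("Phenotype",),
            "GeneVariant": ("Variant",),
            "Haplotype": ("Variant",),
            "Genotype": ("Variant",),
            **{label: ("ReactionLikeEvent",) for label in REACTION_LIKE_LABELS},
        }
    )

    def __post_init__(self):
        for label in self.parents:
            self.closure(label)  # raises on cycles

    def closure(self, label: str) -> set[str]:
        """All ancestor/grouping labels implied by ``label``."""
        out: set[str] = set()
        frontier = [label]
        while frontier:
            current = frontier.pop()
            for parent in self.parents.get(current, ()):
                if parent == label:
                    raise ContractError(f"label hierarchy cycle through {label!r}")
                if parent not in out:
                    out.add(parent)
                    frontier.append(parent)
        return out


DEFAULT_HIERARCHY = LabelHierarchy()


def apply_label_hierarchy(
    store: GraphStore, hierarchy: LabelHierarchy = DEFAULT_HIERARCHY
) -> int:
    """Add every implied ancestor/grouping label; idempotent.  Returns the
    number of label additions."""
    added = 0
    for node_id in sorted(store.nodes):
        node = store.nodes[node_id]
        implied: set[str] = set()
        for label in node.labels:
            implied |= hierarchy.closure(label)
        for label in sorted(implied - set(node.labels)):
            store.add_label(node_id, label)
            added += 1
    return added


def apply_renames(store: GraphStore, rename_map: dict[str, str] | None = None) -> int:
    """Retype every edge of an old type to its new type; returns count."""
    rename_map = DEFAULT_RENAMES if rename_map is None else rename_map
    renamed = 0
    for edge in store.edges.values():
        new_type = rename_map.get(edge.type_name)
        if new_type is not None:
            edge.type_name = new_type
            renamed += 1
    return renamed


def _split_cell(value: str, delimiter: str = LIST_DELIMITER):
    value = str(value)
    if delimiter in value:
        return [v for v in value.split(delimiter) if v != ""]
    return value


def _row_properties(row: pd.Series, delimiter: str = LIST_DELIMITER) -> dict:
    return {
        col: _split_cell(val, delimiter)
        for col, val in row.items()
        if str(val) != "" and not col.startswith("_")
    }


def replace_or_remove_nodes(
    store: GraphStore,
    label: str,
    replacement: pd.DataFrame,
    match_column: str = "identifier",
    node_properties: tuple[str, ...] = ("identifier",),
    extra_labels: tuple[str, ...] = (),
) -> tuple[int, int, int]:
    """Replace the ``label`` node set with the replacement table.

    Rows match existing nodes through ``match_column`` values (list cells
    allowed) against the listed node properties, or directly through the
    row identifier.  Matched nodes keep their surrogate id — hence every
    incident edge — while their properties are replaced by the row's.
    Unmatched existing nodes are removed together with incident edges;
    unmatched rows become new nodes.  Returns (replaced, removed, created).
    """
    if match_column not in replacement.columns:
        raise ContractError(f"replacement table lacks match column {match_column!r}")
    keys = replacement[match_column].astype(str)
    keys = keys[keys != ""]
    if keys.duplicated().any():
        dupes = sorted(keys[keys.duplicated()].unique())
        raise ContractError(f"duplicate match keys in replacement table: {dupes}")

    matched_rows: dict[int, str] = {}
    claimed: set[str] = set()
    for pos, row in replacement.iterrows():
        values = _split_cell(row[match_column])
        values = values if isinstance(values, list) else [values]
        ident = str(row.get("identifier", ""))
        if ident:
            values.append(ident)
        candidates: list[str] = []
        for prop in node_properties:
            for value in values:
                candidates.extend(store.lookup(label, prop, value))
        candidates.extend(store.lookup(label, "identifier", ident) if ident else [])
        for node_id in sorted(set(candidates)):
            if node_id not in claimed:
                matched_rows[pos] = node_id
                claimed.add(node_id)
                break

    removed = 0
    for node in list(store.nodes_with_label(label)):
        if node.node_id not in claimed and label == node.primary_label:
            store.remove_node(node.node_id)
            removed += 1

    replaced = created = 0
    for pos, row in replacement.iterrows():
        props = _row_properties(row)
        if pos in matched_rows:
            node_id = matched_rows[pos]
            node = store.nodes[node_id]
            labels = tuple(dict.fromkeys(node.labels + tuple(extra_labels)))
            store.set_properties(node_id, props)
            for extra in labels:
                store.add_label(node_id, extra)
            replaced += 1
        else:
            store.add_node((label,) + tuple(extra_labels), props)
            created += 1
    return replaced, removed, created


def _union_property(existing, incoming):
    old = existing if isinstance(existing, list) else [existing]
    new = incoming if isinstance(incoming, list) else [incoming]
    return old + [v for v in new if v not in old]


def merge_properties(
    store_props: dict, incoming: dict, source: str | None = None
) -> dict:
    """Union two property maps: lists are unioned, missing keys added, and
    conflicting scalars keep the existing value with the incoming one
    stored under ``<name>_<source>``."""
    merged = dict(store_props)
    for key, value in incoming.items():
        if key == "resource":
            continue
        if key not in merged:
            merged[key] = value
        elif isinstance(merged[key], list) or isinstance(value, list):
            merged[key] = _union_property(merged[key], value)
        elif merged[key] != value and source:
            merged[f"{key}_{source.lower()}"] = value
    return merged


def mark_resource(
    store: GraphStore, node_id: str, source: str, tag_properties: dict | None = None
) -> None:
    """Record that ``source`` contributed to a node: extend the resource
    list and attach the source-prefixed tag properties."""
    node = store.nodes[node_id]
    resource = node.properties.get("resource", [])
    resource = resource if isinstance(resource, list) else [resource]
    if source not in resource:
        resource = resource + [source]
    updates = {"resource": resource}
    prefix = source.lower()
    has_tag = any(name.startswith(prefix + "_") for name in node.properties)
    if tag_properties:
        for name, value in tag_properties.items():
            tagged = name if name.startswith(prefix + "_") else f"{prefix}_{name}"
            updates[tagged] = value
            has_tag = True
    if not has_tag:
        updates[f"{prefix}_resource"] = "true"
    store.update_properties(node_id, updates)


def update_node(
    store: GraphStore,
    node_id: str,
    properties: dict,
    source: str,
    tag_properties: dict | None = None,
) -> None:
    """Match-and-update path: merge properties and record provenance."""
    node = store.nodes[node_id]
    store.set_properties(node_id, merge_properties(node.properties, properties, source))
    mark_resource(store, node_id, source, tag_properties)


def merge_edge(
    store: GraphStore,
    source_id: str,
    target_id: str,
    type_name: str,
    properties: dict | None = None,
    match_on: tuple[str, ...] = (),
    source: str | None = None,
) -> str:
    """Match-or-create an edge; returns "created" or "updated".

    An existing edge matches when type and endpoints agree and every
    ``match_on`` property value coincides.  On update, properties are
    unioned and the resource list extended.
    """
    properties = dict(properties or {})
    for edge in store.out_edges(source_id):
        if edge.target_id != target_id or edge.type_name != type_name:
            continue
        if any(edge.properties.get(k) != properties.get(k) for k in match_on):
            continue
        merged = merge_properties(edge.properties, properties, source)
        if source:
            resource = edge.properties.get("resource", [])
            resource = resource if isinstance(resource, list) else [resource]
            if source not in resource:
                resource = resource + [source]
            merged["resource"] = resource
            merged[f"{source.lower()}_resource"] = "true"
        edge.properties = merged
        return "updated"
    if source:
        properties.setdefault("resource", [source])
        properties.setdefault(f"{source.lower()}_resource", "true")
    store.add_edge(type_name, source_id, target_id, properties)
    return "created"


EDGE_NODE_LABELS = ("Interaction", "Treatment", "ClinicalAnnotation", "VariantAnnotation")


def create_edge_node(
    store: GraphStore,
    label: str,
    participants: list[tuple[str, str]],
    properties: dict | None = None,
    registry: AbbreviationRegistry = DEFAULT_REGISTRY,
) -> str:
    """Reify a >2-ary connection as an edge-node plus one edge per
    participant.

    ``participants`` holds (node id, edge type) pairs; each edge type must
    parse under the naming grammar, and its abbreviations decide whether
    the edge-node is that edge's source or target (an interaction yields
    both ``INTERACTS_IiP`` and ``INTERACTS_PiI`` edges).
    """
    if label not in EDGE_NODE_LABELS:
        raise ContractError(f"{label!r} is not an edge-node label")
    if len(participants) < 2:
        raise ContractError("an edge-node needs at least 2 participants")
    own_abbrev = registry.abbreviate(label)
    plan: list[tuple[str, str, bool]] = []
    for node_id, type_name in participants:
        parsed = parse_edge_type(type_name, registry)
        if not parsed:
            raise ContractError(f"participant edge type invalid: {parsed.reason}")
        if parsed.src_abbrev == own_abbrev:
            plan.append((node_id, type_name, True))  # edge-node -> participant
        elif parsed.dst_abbrev == own_abbrev:
            plan.append((node_id, type_name, False))
        else:
            raise ContractError(
                f"edge type {type_name!r} does not involve the {label!r} abbreviation"
            )
    node_id = store.add_node((label,), dict(properties or {}))
    for participant, type_name, outgoing in plan:
        if outgoing:
            store.add_edge(type_name, node_id, participant)
        else:
            store.add_edge(type_name, participant, node_id)
    return node_id


# ------------------------------------------------------ EQUAL / allele edges

#: (source label, target label, edge type) in priority order; specific
#: labels are preferred over the Phenotype grouping fallback.
EQUAL_EDGE_TYPES = (
    ("Disease", "SideEffect", "EQUAL_DeSE"),
    ("Disease", "Symptom", "EQUAL_DeS"),
    ("Symptom", "SideEffect", "EQUAL_SeSE"),
    ("Phenotype", "SideEffect", "EQUAL_PTeSE"),
)

PHENOTYPE_CLASS_LABELS = ("Disease", "Symptom", "SideEffect", "Phenotype")


def _shared_keys(node: PropertyNode, umls_property: str) -> set[str]:
    keys: set[str] = set()
    umls = node.properties.get(umls_property)
    if umls:
        values = umls if isinstance(umls, list) else [umls]
        keys.update(f"umls:{v}" for v in values)
    name = node.properties.get("name")
    if name:
        keys.add(f"name:{normalize_name(str(name))}")
    return keys


def generate_equal_edges(
    store: GraphStore, umls_property: str = "umls_id"
) -> int:
    """Link phenotype-class nodes of equal meaning.

    For each cross-label pair among Disease/Symptom/SideEffect/Phenotype
    sharing a UMLS identifier or a normalized name, one EQUAL edge of the
    matching type is created (no duplicates, no self-loops).  Node pairs
    that already carry an EQUAL edge are skipped, so the operation is
    idempotent.
    """
    groups: dict[str, set[str]] = {}
    for label in PHENOTYPE_CLASS_LABELS:
        for node in store.nodes_with_label(label):
            for key in _shared_keys(node, umls_property):
                groups.setdefault(key, set()).add(node.node_id)

    existing_pairs = {
        frozenset((e.source_id, e.target_id))
        for e in store.edges.values()
        if e.type_name.startswith("EQUAL_")
    }
    created = 0
    seen: set[frozenset] = set()
    for key in sorted(groups):
        members = sorted(
            groups[key], key=lambda n: (store.nodes[n].identifier or "", n)
        )
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pair = frozenset((members[i], members[j]))
                if pair in seen or pair in existing_pairs:
                    continue
                edge = _equal_edge_for(store, members[i], members[j])
                if edge is None:
                    continue
                src, dst, type_name = edge
                store.add_edge(type_name, src, dst, {"match_key": key})
                seen.add(pair)
                created += 1
    return created


def _equal_edge_for(store: GraphStore, a: str, b: str):
    labels_a = set(store.nodes[a].labels)
    labels_b = set(store.nodes[b].labels)
    for src_label, dst_label, type_name in EQUAL_EDGE_TYPES:
        # skip symmetric cases (both nodes carry both labels): that is a
        # same-class pair, for which no EQUAL type exists
        if (
            src_label in labels_a and dst_label in labels_b
            and not (src_label in labels_b and dst_label in labels_a)
        ):
            return a, b, type_name
        if (
            src_label in labels_b and dst_label in labels_a
            and not (src_label in labels_a and dst_label in labels_b)
        ):
            return b, a, type_name
    return None


def generate_allele_edges(store: GraphStore, rs_property: str = "rs_id") -> int:
    """Pairwise IS_ALLEL_OF_ViaoV edges between Variant nodes sharing an
    rs-identifier; one edge per unordered pair, lexicographically smaller
    identifier as source.  Idempotent."""
    groups: dict[str, set[str]] = {}
    for node in store.nodes_with_label("Variant"):
        value = node.properties.get(rs_property)
        if not value:
            continue
        values = value if isinstance(value, list) else [value]
        for rs in values:
            groups.setdefault(str(rs), set()).add(node.node_id)
    existing = {
        frozenset((e.source_id, e.target_id))
        for e in store.edges.values()
        if e.type_name == "IS_ALLEL_OF_ViaoV"
    }
    created = 0
    for rs in sorted(groups):
        members = sorted(
            groups[rs], key=lambda n: (store.nodes[n].identifier or "", n)
        )
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pair = frozenset((members[i], members[j]))
                if pair in existing:
                    continue
                store.add_edge(
                    "IS_ALLEL_OF_ViaoV", members[i], members[j], {"rs_id": rs}
                )
                existing.add(pair)
                created += 1
    return created


# ----------------------------------------------------------------- the plan


@dataclass(frozen=True)
class MergePlan:
    """Ordered (source name, routine name) pairs; the default order runs
    ontology and gene updates first, then proteins and events, then
    chemicals and their dependents, and closes with cross-cutting edges."""

    steps: tuple[tuple[str, str], ...]


def run_merge(store: GraphStore, plan: MergePlan, routines: dict, context) -> dict:
    """Execute the plan in order; each routine resolves entities and applies
    node/edge merges.  Returns a report with per-source counts.  A routine
    failure aborts with the plan position."""
    report: dict = {"steps": []}
    for position, (source_name, routine_name) in enumerate(plan.steps):
        routine = routines.get(routine_name)
        if routine is None:
            raise ForgeError(
                f"merge plan step {position} ({source_name}): "
                f"unknown routine {routine_name!r}"
            )
        try:
            counts = routine(store, context) or {}
        except Exception as exc:
            raise ForgeError(
                f"merge plan aborted at step {position} ({source_name}): {exc}"
            ) from exc
        report["steps"].append(
            {"position": position, "source": source_name,
             "routine": routine_name, "counts": counts}
        )
    return report
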