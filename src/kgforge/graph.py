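"""In-memory labelled property graph with indexed lookup and path search.

Nodes carry an ordered set of labels and a property map whose values are
scalars (str/int/float/bool) or lists of scalars.  Node identity in the
store is the pair (primary label, ``identifier`` property); a surrogate
id (``n0``, ``n1``, ...) is generated internally so that replacing a
node's properties during merging never breaks incident edges.

Table loading follows the TSV conventions of ontology exports: UTF-8,
tab-separated, first row header, ``|`` as the list delimiter.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import ContractError, FormatError

logger = logging.getLogger(__name__)

#: Delimiter splitting list-valued TSV cells.
LIST_DELIMITER = "|"

Scalar = str | int | float | bool
PropertyValue = Scalar | list


@dataclass
class PropertyNode:
    """Labelled multi-identifier node with resource provenance.

    ``properties`` conventionally includes ``identifier`` (primary id,
    unique within the primary label), ``resource`` (list of contributing
    source names) and, for source-subgraph nodes only, ``source``.
    """

    node_id: str
    labels: tuple[str, ...]
    properties: dict[str, PropertyValue] = field(default_factory=dict)

    @property
    def primary_label(self) -> str:
        return self.labels[0]

    @property
    def identifier(self) -> str | None:
        value = self.properties.get("identifier")
        return None if value is None else str(value)


@dataclass
class PropertyEdge:
    """Typed, directed edge with provenance and evidence properties."""

    edge_id: str
    type_name: str
    source_id: str
    target_id: str
    properties: dict[str, PropertyValue] = field(default_factory=dict)


@dataclass(frozen=True)
class NodeConstraint:
    label: str | None = None
    props: tuple[tuple[str, Scalar], ...] = ()

    @staticmethod
    def of(label: str | None = None, **props: Scalar) -> "NodeConstraint":
        return NodeConstraint(label, tuple(sorted(props.items())))


@dataclass(frozen=True)
class EdgeConstraint:
    type_name: str | None = None
    direction: str = "out"  # "out" | "in" | "any"


@dataclass(frozen=True)
class PathPattern:
    """Alternating node/edge constraints; starts and ends with a node."""

    steps: tuple

    def __post_init__(self):
        steps = self.steps
        if len(steps) % 2 == 0 or not steps:
            raise ContractError("pattern must alternate node/edge and end on a node")
        for i, step in enumerate(steps):
            expected = NodeConstraint if i % 2 == 0 else EdgeConstraint
            if not isinstance(step, expected):
                raise ContractError(f"step {i} must be a {expected.__name__}")


class GraphStore:
    """Collection of nodes and edges with (label, property) -> value indices."""

    def __init__(self):
        self.nodes: dict[str, PropertyNode] = {}
        self.edges: dict[str, PropertyEdge] = {}
        self._out: dict[str, set[str]] = {}
        self._in: dict[str, set[str]] = {}
        self._by_label: dict[str, set[str]] = {}
        self._indices: dict[tuple[str, str], dict[Scalar, set[str]]] = {}
        self._node_counter = 0
        self._edge_counter = 0

    # ------------------------------------------------------------------ nodes

    def _next_node_id(self) -> str:
        nid = f"n{self._node_counter}"
        self._node_counter += 1
        return nid

    def add_node(
        self,
        labels: Iterable[str],
        properties: dict[str, PropertyValue] | None = None,
        node_id: str | None = None,
    ) -> str:
        labels = tuple(dict.fromkeys(labels))
        if not labels:
            raise ContractError("a node needs at least one label")
        if node_id is None:
            node_id = self._next_node_id()
        elif node_id in self.nodes:
            raise ContractError(f"node id {node_id!r} already exists")
        else:
            self._bump_counter(node_id, "n")
        node = PropertyNode(node_id, labels, dict(properties or {}))
        self.nodes[node_id] = node
        self._out[node_id] = set()
        self._in[node_id] = set()
        for label in labels:
            self._by_label.setdefault(label, set()).add(node_id)
        self._index_node(node)
        return node_id

    def _bump_counter(self, explicit_id: str, prefix: str) -> None:
        if explicit_id.startswith(prefix) and explicit_id[len(prefix):].isdigit():
            n = int(explicit_id[len(prefix):]) + 1
            if prefix == "n":
                self._node_counter = max(self._node_counter, n)
            else:
                self._edge_counter = max(self._edge_counter, n)

    def remove_node(self, node_id: str) -> None:
        node = self.nodes[node_id]
        for eid in sorted(self._out[node_id] | self._in[node_id]):
            if eid in self.edges:
                self.remove_edge(eid)
        self._unindex_node(node)
        for label in node.labels:
            self._by_label[label].discard(node_id)
        del self._out[node_id], self._in[node_id], self.nodes[node_id]

    def add_label(self, node_id: str, label: str) -> bool:
        """Add ``label`` to a node; returns True when newly added."""
        node = self.nodes[node_id]
        if label in node.labels:
            return False
        self._unindex_node(node)
        node.labels = node.labels + (label,)
        self._by_label.setdefault(label, set()).add(node_id)
        self._index_node(node)
        return True

    def set_properties(self, node_id: str, properties: dict[str, PropertyValue]) -> None:
        """Replace a node's property map, keeping surrogate id and edges."""
        node = self.nodes[node_id]
        self._unindex_node(node)
        node.properties = dict(properties)
        self._index_node(node)

    def update_properties(self, node_id: str, properties: dict[str, PropertyValue]) -> None:
        node = self.nodes[node_id]
        merged = dict(node.properties)
        merged.update(properties)
        self.set_properties(node_id, merged)

    # ------------------------------------------------------------------ edges

    def add_edge(
        self,
        type_name: str,
        source_id: str,
        target_id: str,
        properties: dict[str, PropertyValue] | None = None,
        edge_id: str | None = None,
    ) -> str:
        if source_id not in self.nodes or target_id not in self.nodes:
            raise ContractError(
                f"edge {type_name!r} endpoints {source_id!r}->{target_id!r} must exist"
            )
        if edge_id is None:
            edge_id = f"e{self._edge_counter}"
            self._edge_counter += 1
        elif edge_id in self.edges:
            raise ContractError(f"edge id {edge_id!r} already exists")
        else:
            self._bump_counter(edge_id, "e")
        self.edges[edge_id] = PropertyEdge(
            edge_id, type_name, source_id, target_id, dict(properties or {})
        )
        self._out[source_id].add(edge_id)
        self._in[target_id].add(edge_id)
        return edge_id

    def remove_edge(self, edge_id: str) -> None:
        edge = self.edges.pop(edge_id)
        self._out[edge.source_id].discard(edge_id)
        self._in[edge.target_id].discard(edge_id)

    def out_edges(self, node_id: str) -> list[PropertyEdge]:
        return [self.edges[e] for e in sorted(self._out[node_id])]

    def in_edges(self, node_id: str) -> list[PropertyEdge]:
        return [self.edges[e] for e in sorted(self._in[node_id])]

    def degree(self, node_id: str) -> int:
        return len(self._out[node_id]) + len(self._in[node_id])

    # ---------------------------------------------------------------- queries

    def labels(self) -> list[str]:
        return sorted(l for l, ids in self._by_label.items() if ids)

    def nodes_with_label(self, label: str) -> list[PropertyNode]:
        return [self.nodes[n] for n in sorted(self._by_label.get(label, ()))]

    def edge_types(self) -> list[str]:
        return sorted({e.type_name for e in self.edges.values()})

    def edges_of_type(self, type_name: str) -> list[PropertyEdge]:
        return [e for _, e in sorted(self.edges.items()) if e.type_name == type_name]

    # ---------------------------------------------------------------- indices

    def create_index(self, label: str, prop: str) -> None:
        key = (label, prop)
        if key in self._indices:
            return
        index: dict[Scalar, set[str]] = {}
        for nid in self._by_label.get(label, ()):
            self._index_entry(index, nid, self.nodes[nid].properties.get(prop))
        self._indices[key] = index

    @staticmethod
    def _index_entry(index: dict, node_id: str, value: PropertyValue | None) -> None:
        if value is None:
            return
        values = value if isinstance(value, list) else [value]
        for v in values:
            index.setdefault(v, set()).add(node_id)

    def _index_node(self, node: PropertyNode) -> None:
        for (label, prop), index in self._indices.items():
            if label in node.labels:
                self._index_entry(index, node.node_id, node.properties.get(prop))

    def _unindex_node(self, node: PropertyNode) -> None:
        for (label, prop), index in self._indices.items():
            if label in node.labels:
                value = node.properties.get(prop)
                if value is None:
                    continue
                values = value if isinstance(value, list) else [value]
                for v in values:
                    bucket = index.get(v)
                    if bucket is not None:
                        bucket.discard(node.node_id)
                        if not bucket:
                            del index[v]

    def lookup(self, label: str, prop: str, value: Scalar) -> list[str]:
        """Indexed node ids for (label, prop, value); builds the index on demand."""
        self.create_index(label, prop)
        return sorted(self._indices[(label, prop)].get(value, ()))

    def index_definitions(self) -> list[tuple[str, str]]:
        return sorted(self._indices)

    # ------------------------------------------------------------------ stats

    def node_count(self) -> int:
        return len(self.nodes)

    def edge_count(self) -> int:
        return len(self.edges)

    def copy(self) -> "GraphStore":
        import copy as _copy

        other = GraphStore()
        for nid, node in self.nodes.items():
            other.add_node(node.labels, _copy.deepcopy(node.properties), node_id=nid)
        for eid, edge in self.edges.items():
            other.add_edge(
                edge.type_name,
                edge.source_id,
                edge.target_id,
                _copy.deepcopy(edge.properties),
                edge_id=eid,
            )
        for label, prop in self.index_definitions():
            other.create_index(label, prop)
        return other


# ------------------------------------------------------------------- loading


def _read_table(table, comment: str | None = None) -> pd.DataFrame:
    """Read a TSV path/stream into an all-string frame; pass DataFrames through."""
    if isinstance(table, pd.DataFrame):
        return table.fillna("").astype(str)
    if isinstance(table, (str, Path)):
        handle: io.TextIOBase | str = str(table)
    else:
        handle = table
    return pd.read_csv(
        handle,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        comment=comment,
        encoding="utf-8",
    )


def _cell_to_property(value: str, delimiter: str) -> PropertyValue:
    if delimiter in value:
        return [v for v in value.split(delimiter) if v != ""]
    return value


def load_node_table(
    table,
    label: str,
    store: GraphStore,
    delimiter: str = LIST_DELIMITER,
    duplicate_policy: str = "reject",
    extra_properties: dict[str, PropertyValue] | None = None,
) -> int:
    """Create one node per table row under ``label``; returns nodes created.

    All columns become properties; cells containing ``delimiter`` are split
    into lists.  Duplicate identifiers within the table are rejected by
    default or merged property-wise under ``duplicate_policy="merge"``.
    """
    df = _read_table(table)
    if "identifier" not in df.columns:
        raise FormatError(f"node table for label {label!r} lacks an 'identifier' column")
    if duplicate_policy not in ("reject", "merge"):
        raise ContractError(f"unknown duplicate policy {duplicate_policy!r}")
    store.create_index(label, "identifier")
    created = 0
    for _, row in df.iterrows():
        props: dict[str, PropertyValue] = {
            col: _cell_to_property(val, delimiter)
            for col, val in row.items()
            if val != ""
        }
        if extra_properties:
            props.update(extra_properties)
        ident = str(row["identifier"])
        existing = store.lookup(label, "identifier", ident)
        if existing:
            if duplicate_policy == "reject":
                raise FormatError(f"duplicate identifier {ident!r} in {label!r} table")
            _merge_node_properties(store, existing[0], props)
            continue
        store.add_node([label], props)
        created += 1
    return created


def _merge_node_properties(store: GraphStore, node_id: str, props: dict) -> None:
    node = store.nodes[node_id]
    merged = dict(node.properties)
    for key, value in props.items():
        if key not in merged:
            merged[key] = value
        elif isinstance(merged[key], list) or isinstance(value, list):
            old = merged[key] if isinstance(merged[key], list) else [merged[key]]
            new = value if isinstance(value, list) else [value]
            merged[key] = old + [v for v in new if v not in old]
        # conflicting scalars: first occurrence wins
    store.set_properties(node_id, merged)


def load_edge_table(
    table,
    type_name: str,
    store: GraphStore,
    source_label: str,
    target_label: str,
    source_column: str = "source_id",
    target_column: str = "target_id",
    delimiter: str = LIST_DELIMITER,
    extra_properties: dict[str, PropertyValue] | None = None,
) -> int:
    """Create one edge per row whose endpoints resolve via the identifier index.

    Rows with unresolvable endpoints are skipped and logged with the reason
    (integration must survive partial source sets); the return value counts
    edges actually created.
    """
    df = _read_table(table)
    for col in (source_column, target_column):
        if col not in df.columns:
            raise FormatError(f"edge table for {type_name!r} lacks column {col!r}")
    created = 0
    for pos, row in df.iterrows():
        src = store.lookup(source_label, "identifier", str(row[source_column]))
        dst = store.lookup(target_label, "identifier", str(row[target_column]))
        if not src or not dst:
            missing = source_column if not src else target_column
            logger.warning(
                "skipping %s row %s: unresolved %s=%r",
                type_name, pos, missing, str(row[missing]),
            )
            continue
        props = {
            col: _cell_to_property(val, delimiter)
            for col, val in row.items()
            if col not in (source_column, target_column) and val != ""
        }
        if extra_properties:
            props.update(extra_properties)
        store.add_edge(type_name, src[0], dst[0], props)
        created += 1
    return created


# --------------------------------------------------------------- path search


def _node_matches(node: PropertyNode, constraint: NodeConstraint) -> bool:
    if constraint.label is not None and constraint.label not in node.labels:
        return False
    for key, value in constraint.props:
        have = node.properties.get(key)
        if isinstance(have, list):
            if value not in have:
                return False
        elif have != value:
            return False
    return True


def _candidate_steps(
    store: GraphStore, node_id: str, constraint: EdgeConstraint
) -> Iterator[tuple[PropertyEdge, str]]:
    edges: list[tuple[PropertyEdge, str]] = []
    if constraint.direction in ("out", "any"):
        for edge in store.out_edges(node_id):
            edges.append((edge, edge.target_id))
    if constraint.direction in ("in", "any"):
        for edge in store.in_edges(node_id):
            edges.append((edge, edge.source_id))
    if constraint.type_name is not None:
        edges = [(e, n) for e, n in edges if e.type_name == constraint.type_name]
    edges.sort(key=lambda en: (store.nodes[en[1]].identifier or "", en[0].edge_id))
    return iter(edges)


def find_paths(
    store: GraphStore,
    pattern: PathPattern,
    max_results: int | None = None,
) -> list[list[str]]:
    """All walks satisfying the pattern, as alternating node/edge id lists.

    Bounded-depth DFS with lexicographic tie-breaking on node identifiers,
    so the result order is deterministic for a given store.
    """
    steps = pattern.steps
    start_constraint: NodeConstraint = steps[0]
    if start_constraint.label is not None:
        starts = store.nodes_with_label(start_constraint.label)
    else:
        starts = [store.nodes[n] for n in sorted(store.nodes)]
    starts = [n for n in starts if _node_matches(n, start_constraint)]
    starts.sort(key=lambda n: (n.identifier or "", n.node_id))

    results: list[list[str]] = []

    def dfs(node_id: str, step_index: int, trail: list[str]) -> bool:
        if step_index == len(steps):
            results.append(list(trail))
            return max_results is not None and len(results) >= max_results
        edge_constraint: EdgeConstraint = steps[step_index]
        node_constraint: NodeConstraint = steps[step_index + 1]
        for edge, neighbor in _candidate_steps(store, node_id, edge_constraint):
            if not _node_matches(store.nodes[neighbor], node_constraint):
                continue
            trail.extend([edge.edge_id, neighbor])
            if dfs(neighbor, step_index + 2, trail):
                return True
            del trail[-2:]
        return False

    for start in starts:
        if dfs(start.node_id, 1, [start.node_id]):
            break
    return results
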