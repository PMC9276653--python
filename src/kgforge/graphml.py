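"""GraphML reading and writing in the graph-importer dialect.

Node labels are stored in a string attribute ``labels`` as a ":"-prefixed
concatenation (``:Chemical:Compound``); the edge type is stored in the
attribute ``label``.  Scalars are declared with the native GraphML
``attr.type``s; list-valued properties are declared with an additional
``attr.list`` attribute on their <key> element and serialized as JSON
arrays, the convention of Neo4j-style GraphML exports.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

from lxml import etree

from .errors import FormatError
from .graph import GraphStore

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"
_Q = "{%s}" % GRAPHML_NS

_SCALAR_TYPES = {bool: "boolean", int: "long", float: "double", str: "string"}
_PARSERS = {
    "boolean": lambda s: s == "true",
    "int": int,
    "long": int,
    "float": float,
    "double": float,
    "string": str,
}


def _value_type(value) -> tuple[str, bool]:
    """(attr.type, is_list) for a property value."""
    if isinstance(value, list):
        inner = {type(v) for v in value}
        if len(inner) == 1 and (t := inner.pop()) in _SCALAR_TYPES and t is not bool:
            return _SCALAR_TYPES[t], True
        return "string", True
    for t, name in _SCALAR_TYPES.items():
        if isinstance(value, t):
            return name, False
    return "string", False


def _merge_type(a: tuple[str, bool] | None, b: tuple[str, bool]) -> tuple[str, bool]:
    if a is None or a == b:
        return b
    # mixed declarations degrade to string, list-ness is sticky
    return "string", a[1] or b[1]


def _collect_keys(entities) -> dict[str, tuple[str, bool]]:
    keys: dict[str, tuple[str, bool]] = {}
    for entity in entities:
        for name, value in entity.properties.items():
            keys[name] = _merge_type(keys.get(name), _value_type(value))
    return keys


def _serialize(value, attr_type: str, is_list: bool) -> str:
    if is_list:
        items = value if isinstance(value, list) else [value]
        return json.dumps(items, ensure_ascii=False)
    if attr_type == "boolean":
        return "true" if value else "false"
    return str(value)


def write_graphml(store: GraphStore, dest) -> None:
    """Serialize ``store`` to ``dest`` (path or binary stream)."""
    root = etree.Element(_Q + "graphml", nsmap={None: GRAPHML_NS})
    node_keys = _collect_keys(store.nodes.values())
    edge_keys = _collect_keys(store.edges.values())

    key_ids: dict[tuple[str, str], str] = {}

    def declare(domain: str, name: str, attr_type: str, is_list: bool) -> str:
        kid = f"{domain[0]}_{name}"
        el = etree.SubElement(root, _Q + "key", id=kid)
        el.set("for", domain)
        el.set("attr.name", name)
        el.set("attr.type", attr_type)
        if is_list:
            el.set("attr.list", attr_type)
        key_ids[(domain, name)] = kid
        return kid

    declare("node", "labels", "string", False)
    declare("edge", "label", "string", False)
    for name, (attr_type, is_list) in sorted(node_keys.items()):
        declare("node", name, attr_type, is_list)
    for name, (attr_type, is_list) in sorted(edge_keys.items()):
        declare("edge", name, attr_type, is_list)

    graph = etree.SubElement(root, _Q + "graph", id="G", edgedefault="directed")
    for node in store.nodes.values():
        el = etree.SubElement(graph, _Q + "node", id=node.node_id)
        data = etree.SubElement(el, _Q + "data", key=key_ids[("node", "labels")])
        data.text = "".join(f":{label}" for label in node.labels)
        for name, value in node.properties.items():
            attr_type, is_list = node_keys[name]
            d = etree.SubElement(el, _Q + "data", key=key_ids[("node", name)])
            d.text = _serialize(value, attr_type, is_list)
    for edge in store.edges.values():
        el = etree.SubElement(
            graph, _Q + "edge", id=edge.edge_id, source=edge.source_id, target=edge.target_id
        )
        data = etree.SubElement(el, _Q + "data", key=key_ids[("edge", "label")])
        data.text = edge.type_name
        for name, value in edge.properties.items():
            attr_type, is_list = edge_keys[name]
            d = etree.SubElement(el, _Q + "data", key=key_ids[("edge", name)])
            d.text = _serialize(value, attr_type, is_list)

    tree = etree.ElementTree(root)
    if isinstance(dest, (str, Path)):
        tree.write(str(dest), xml_declaration=True, encoding="UTF-8", pretty_print=True)
    else:
        tree.write(dest, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _parse_value(text: str | None, attr_type: str, list_type: str | None):
    if text is None:
        text = ""
    if list_type is not None:
        try:
            items = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"malformed list value {text!r}: {exc}") from exc
        return list(items)
    return _PARSERS[attr_type](text)


def read_graphml(src) -> GraphStore:
    """Parse GraphML from ``src`` (path or stream) into a fresh GraphStore."""
    try:
        if isinstance(src, (str, Path)):
            tree = etree.parse(str(src))
        else:
            tree = etree.parse(src)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed GraphML (line {exc.lineno}): {exc.msg}") from exc
    root = tree.getroot()

    keys: dict[str, tuple[str, str, str | None]] = {}  # id -> (name, type, list type)
    for key in root.findall(_Q + "key"):
        attr_type = key.get("attr.type", "string")
        if attr_type not in _PARSERS:
            raise FormatError(f"unknown GraphML attribute type {attr_type!r}")
        keys[key.get("id")] = (key.get("attr.name"), attr_type, key.get("attr.list"))

    store = GraphStore()
    graph = root.find(_Q + "graph")
    if graph is None:
        raise FormatError("GraphML document has no <graph> element")

    for el in graph.findall(_Q + "node"):
        labels: list[str] = []
        props = {}
        for data in el.findall(_Q + "data"):
            name, attr_type, list_type = keys[data.get("key")]
            if name == "labels":
                labels = [l for l in (data.text or "").split(":") if l]
            else:
                props[name] = _parse_value(data.text, attr_type, list_type)
        if not labels:
            raise FormatError(f"node {el.get('id')!r} carries no labels attribute")
        store.add_node(labels, props, node_id=el.get("id"))

    for el in graph.findall(_Q + "edge"):
        type_name = None
        props = {}
        for data in el.findall(_Q + "data"):
            name, attr_type, list_type = keys[data.get("key")]
            if name == "label":
                type_name = data.text or ""
            else:
                props[name] = _parse_value(data.text, attr_type, list_type)
        if type_name is None:
            raise FormatError(f"edge {el.get('id')!r} carries no label attribute")
        store.add_edge(
            type_name, el.get("source"), el.get("target"), props, edge_id=el.get("id")
        )
    return store


def graphml_bytes(store: GraphStore) -> bytes:
    buffer = io.BytesIO()
    write_graphml(store, buffer)
    return buffer.getvalue()
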