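"""Entity resolution: map incoming source records onto existing graph nodes.

Resolution runs an ordered cascade of strategies — exact identifier
lookup, cross-reference-table bridging (the stand-in for licensed mapping
systems such as UMLS/RxNorm), normalized name/synonym comparison, and
chemical-structure similarity — and stops at the first strategy that
yields candidates.  Ambiguous results (more than one candidate) are never
auto-merged; downstream merging treats them as unmatched and the mapping
report surfaces them for manual review, together with unique matches
whose names disagree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import ContractError
from .graph import GraphStore

_PUNCT_RE = re.compile(r"[.,;:–—'’]")
_WS_RE = re.compile(r"\s+")


def normalize_name(raw: str) -> str:
    """Canonicalize a name for comparison: lowercase, trim, collapse
    internal whitespace, strip a fixed punctuation set.  Idempotent."""
    text = _PUNCT_RE.sub("", str(raw))
    text = _WS_RE.sub(" ", text).strip()
    return text.lower()


def strip_namespace(value: str, prefixes: tuple[str, ...] = ()) -> str:
    """Unify CURIE spellings by removing a configured namespace prefix
    (``MONDO:0001`` vs ``0001``)."""
    text = str(value)
    for prefix in prefixes:
        if text.upper().startswith(prefix.upper() + ":"):
            return text[len(prefix) + 1:]
    return text


@dataclass(frozen=True)
class MappingStrategy:
    """One resolution strategy: how to compare a source entity to nodes.

    ``kind`` is one of identifier / xref / name / structure; ``key`` names
    the entity property (and node property, unless ``node_property``
    differs) carrying the compared value.
    """

    kind: str
    key: str
    node_property: str | None = None
    normalize: bool = False
    xref_table: str | None = None  # name of the XrefTable bridging namespaces
    namespace_prefixes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("identifier", "xref", "name", "structure"):
            raise ContractError(f"unknown strategy kind {self.kind!r}")

    @property
    def target_property(self) -> str:
        return self.node_property or self.key


@dataclass(frozen=True)
class MappingCascade:
    """Ordered strategies resolving one entity class onto a target label."""

    entity_class: str
    target_label: str
    strategies: tuple[MappingStrategy, ...]

    def __post_init__(self):
        if not self.strategies:
            raise ContractError("cascade needs at least one strategy")
        seen = set()
        for s in self.strategies:
            if (s.kind, s.key) in seen:
                raise ContractError(f"duplicate strategy ({s.kind}, {s.key}) in cascade")
            seen.add((s.kind, s.key))
        if any(s.kind == "structure" for s in self.strategies):
            if self.target_label not in ("Chemical", "Compound", "Salt"):
                raise ContractError("structure strategies only apply to chemical targets")


@dataclass
class MappingResult:
    """Outcome of resolving one entity: unique, ambiguous, or unmatched."""

    entity_id: str
    matched: list[str] = field(default_factory=list)
    strategy: MappingStrategy | None = None
    entity_name: str = ""

    @property
    def status(self) -> str:
        if len(self.matched) == 1:
            return "unique"
        return "ambiguous" if self.matched else "unmatched"

    @property
    def node_id(self) -> str | None:
        return self.matched[0] if self.status == "unique" else None


class XrefTable:
    """Deduplicated (id-in-A, id-in-B) pairs bridging two namespaces."""

    def __init__(self, namespace_a: str, namespace_b: str, pairs):
        self.namespace_a = namespace_a
        self.namespace_b = namespace_b
        seen = set()
        self._forward: dict[str, list[str]] = {}
        for a, b in pairs:
            a, b = str(a), str(b)
            if a == b or (a, b) in seen:
                continue
            seen.add((a, b))
            self._forward.setdefault(a, []).append(b)

    @staticmethod
    def from_table(table: pd.DataFrame, namespace_a: str, namespace_b: str) -> "XrefTable":
        return XrefTable(
            namespace_a, namespace_b,
            zip(table[namespace_a].astype(str), table[namespace_b].astype(str)),
        )

    def bridge(self, identifier: str) -> list[str]:
        return list(self._forward.get(str(identifier), []))


def build_identifier_index(
    store: GraphStore, label: str, key_property: str, normalize: bool = False
) -> dict[str, set[str]]:
    """Complete value -> node-id map over every node of ``label`` carrying
    the key property (list-valued properties index each element)."""
    index: dict[str, set[str]] = {}
    for node in store.nodes_with_label(label):
        value = node.properties.get(key_property)
        if value is None:
            continue
        values = value if isinstance(value, list) else [value]
        for v in values:
            key = normalize_name(v) if normalize else str(v)
            index.setdefault(key, set()).add(node.node_id)
    return index


def resolve_via_xref(
    entity_id: str, table: XrefTable, index: dict[str, set[str]]
) -> list[str]:
    """Candidates reached by bridging ``entity_id`` through the xref table
    into the node index; deduplicated, sorted."""
    candidates: set[str] = set()
    for bridged in table.bridge(entity_id):
        candidates.update(index.get(bridged, ()))
    return sorted(candidates)


def _entity_values(entity: dict, key: str) -> list[str]:
    value = entity.get(key)
    if value is None or value == "":
        return []
    return [str(v) for v in (value if isinstance(value, list) else [value])]


class Resolver:
    """Caches per-(label, property) indices over one store and resolves
    entities through cascades."""

    def __init__(
        self,
        store: GraphStore,
        xref_tables: dict[str, XrefTable] | None = None,
        similarity_threshold: float = 0.75,
    ):
        self.store = store
        self.xref_tables = dict(xref_tables or {})
        self.similarity_threshold = similarity_threshold
        self._indices: dict[tuple[str, str, bool], dict[str, set[str]]] = {}

    def invalidate(self) -> None:
        """Drop cached indices after the store was mutated."""
        self._indices.clear()

    def _index(self, label: str, prop: str, normalize: bool) -> dict[str, set[str]]:
        key = (label, prop, normalize)
        if key not in self._indices:
            self._indices[key] = build_identifier_index(self.store, label, prop, normalize)
        return self._indices[key]

    def _name_candidates(self, entity: dict, strategy, label: str) -> set[str]:
        candidates: set[str] = set()
        index = self._index(label, "name", True)
        synonym_index = self._index(label, "synonyms", True)
        for value in _entity_values(entity, strategy.key) + _entity_values(
            entity, "synonyms"
        ):
            key = normalize_name(value)
            candidates.update(index.get(key, ()))
            candidates.update(synonym_index.get(key, ()))
        return candidates

    def _structure_candidates(self, entity: dict, strategy, label: str) -> set[str]:
        from . import chem

        values = _entity_values(entity, strategy.key)
        if not values:
            return set()
        try:
            probe = chem.fingerprint(values[0])
        except Exception:
            return set()
        candidates: set[str] = set()
        for node in self.store.nodes_with_label(label):
            smiles = node.properties.get(strategy.target_property)
            if not smiles or isinstance(smiles, list):
                continue
            try:
                other = chem.fingerprint(str(smiles))
            except Exception:
                continue
            if chem.tanimoto(probe, other) >= self.similarity_threshold:
                candidates.add(node.node_id)
        return candidates

    def resolve(self, entity: dict, cascade: MappingCascade) -> MappingResult:
        """Try the cascade's strategies in order; the first one producing
        any candidate wins and later strategies are not consulted."""
        entity_id = str(entity.get("identifier", ""))
        name = str(entity.get("name", ""))
        for strategy in cascade.strategies:
            candidates: set[str] = set()
            if strategy.kind == "identifier":
                index = self._index(
                    cascade.target_label, strategy.target_property, strategy.normalize
                )
                for value in _entity_values(entity, strategy.key):
                    value = strip_namespace(value, strategy.namespace_prefixes)
                    candidates.update(index.get(value, ()))
            elif strategy.kind == "xref":
                table = self.xref_tables.get(strategy.xref_table or strategy.key)
                if table is None:
                    continue
                index = self._index(
                    cascade.target_label, strategy.target_property, False
                )
                for value in _entity_values(entity, strategy.key):
                    candidates.update(resolve_via_xref(value, table, index))
            elif strategy.kind == "name":
                candidates = self._name_candidates(entity, strategy, cascade.target_label)
            elif strategy.kind == "structure":
                candidates = self._structure_candidates(
                    entity, strategy, cascade.target_label
                )
            if candidates:
                return MappingResult(entity_id, sorted(candidates), strategy, name)
        return MappingResult(entity_id, [], None, name)


def resolve(
    entity: dict,
    cascade: MappingCascade,
    store: GraphStore,
    xref_tables: dict[str, XrefTable] | None = None,
) -> MappingResult:
    """One-shot resolution of a single entity (builds fresh indices)."""
    return Resolver(store, xref_tables).resolve(entity, cascade)


def mapping_report(
    results: list[MappingResult], store: GraphStore | None = None
) -> dict:
    """Per-strategy unique/ambiguous/unmatched counts plus the review list
    of unique matches whose normalized names differ from the node's."""
    counts: dict[str, dict[str, int]] = {}
    review: list[dict] = []
    for result in results:
        strategy_key = (
            f"{result.strategy.kind}:{result.strategy.key}" if result.strategy else "-"
        )
        bucket = counts.setdefault(
            strategy_key, {"unique": 0, "ambiguous": 0, "unmatched": 0}
        )
        bucket[result.status] += 1
        if result.status == "unique" and store is not None and result.entity_name:
            node = store.nodes[result.matched[0]]
            node_name = str(node.properties.get("name", ""))
            if normalize_name(node_name) != normalize_name(result.entity_name):
                review.append(
                    {
                        "entity_id": result.entity_id,
                        "entity_name": result.entity_name,
                        "node_id": result.matched[0],
                        "node_name": node_name,
                        "strategy": strategy_key,
                    }
                )
    total = {"unique": 0, "ambiguous": 0, "unmatched": 0}
    for bucket in counts.values():
        for status, n in bucket.items():
            total[status] += n
    return {"by_strategy": counts, "total": total, "review": review}
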