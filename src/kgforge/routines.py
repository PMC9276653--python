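"""Per-source merge routines executed by the merge plan.

Each routine reads one integrated source subgraph (nodes labelled
``<source>__<label>`` and marked with a ``source`` property), resolves
its entities against the merged schema through the bundled mapping
cascades, and applies the schema merge operations (replace-or-remove,
match-or-create edges, edge-nodes, removals and re-creations).  Routines
are written to be idempotent on the merged graph: re-running the full
plan on its own output changes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources as _resources

import pandas as pd
import yaml

from . import chem
from .graph import GraphStore
from .merge import (
    DEFAULT_HIERARCHY,
    LabelHierarchy,
    apply_label_hierarchy,
    apply_renames,
    create_edge_node,
    generate_allele_edges,
    generate_equal_edges,
    merge_edge,
    replace_or_remove_nodes,
    update_node,
    mark_resource,
)
from .naming import generate_edge_type
from .resolver import MappingCascade, MappingStrategy, Resolver, XrefTable

logger = logging.getLogger(__name__)

RLE_LABELS = ("Reaction", "FailedReaction", "BlackBoxEvent", "Polymerisation",
              "Depolymerisation")

#: CTD/DrugBank interaction tokens -> relation names of the merged schema.
RELATION_TOKENS = {
    "binds": "BINDS",
    "associates": "ASSOCIATES",
    "upregulates": "UPREGULATES",
    "downregulates": "DOWNREGULATES",
    "regulates": "REGULATES",
    "inhibits": "INHIBITS",
    "degenerates": "DEGENERATES",
    "affects_degeneration": "AFFECTS_DEGENERATION",
    "decreases_degeneration": "DECREASES_DEGENERATION",
    "increases_degeneration": "INCREASES_DEGENERATION",
    "is_active_in_metabolism": "IS_ACTIVE_IN_METABOLISM",
    "is_active_on_cellular_level": "IS_ACTIVE_ON_CELLULAR_LEVEL",
    "is_active_on_dna_or_rna_level": "IS_ACTIVE_ON_DNA_OR_RNA_LEVEL",
    "is_active_on_polypeptide_level": "IS_ACTIVE_ON_POLYPEPTIDE_LEVEL",
    "increases": "INCREASES",
    "decreases": "DECREASES",
}

#: Variant-drug association qualifiers -> relation names.
VARIANT_ASSOC_TOKENS = {
    "": "ASSOCIATES",
    "dosage": "ASSOCIATES_TO_DOSAGE",
    "efficacy": "ASSOCIATES_TO_EFFICACY",
    "efficacy_dosage": "ASSOCIATES_TO_EFFICACY_DOSAGE",
    "efficacy_metabolism_pk_dosage": "ASSOCIATES_TO_EFFICACY_METABOLISM_PK_DOSAGE",
    "efficacy_toxicity_adr_dosage": "ASSOCIATES_TO_EFFICACY_TOXICITY_ADR_DOSAGE",
    "metabolism_pk": "ASSOCIATES_TO_METABOLISM_PK",
    "metabolism_pk_dosage": "ASSOCIATES_TO_METABOLISM_PK_DOSAGE",
    "metabolism_pk_toxicity_adr": "ASSOCIATES_TO_METABOLISM_PK_TOXICITY_ADR",
    "toxicity": "ASSOCIATES_TO_TOXICITY",
    "toxicity_adr": "ASSOCIATES_TO_TOXICITY_ADR",
    "toxicity_adr_dosage": "ASSOCIATES_TO_TOXICITY_ADR_DOSAGE",
    "toxicity_adr_efficacy": "ASSOCIATES_TO_TOXICITY_ADR_EFFICACY",
}

#: GAF qualifiers -> annotation relation names.
GAF_QUALIFIERS = {
    "enables": "ENABLES",
    "involved_in": "INVOLVED_IN",
    "located_in": "LOCATED_IN",
    "part_of": "PART_OF",
}

GO_NAMESPACE_LABELS = {
    "biological_process": "BiologicalProcess",
    "cellular_component": "CellularComponent",
    "molecular_function": "MolecularFunction",
}


def load_cascades() -> dict[str, MappingCascade]:
    """The bundled mapping-cascade catalogue (configs/cascades.yaml)."""
    path = _resources.files("kgforge").joinpath("configs/cascades.yaml")
    raw = yaml.safe_load(path.read_text())
    cascades: dict[str, MappingCascade] = {}
    for name, spec in raw.items():
        strategies = tuple(
            MappingStrategy(
                kind=s["kind"],
                key=s["key"],
                node_property=s.get("node_property"),
                xref_table=s.get("xref_table"),
            )
            for s in spec["strategies"]
        )
        cascades[name] = MappingCascade(name, spec["target"], strategies)
    return cascades


@dataclass
class MergeContext:
    """Shared state for one merge run: cascades, xref tables, thresholds."""

    cascades: dict[str, MappingCascade] = field(default_factory=load_cascades)
    xref_tables: dict[str, XrefTable] = field(default_factory=dict)
    hierarchy: LabelHierarchy = field(default_factory=lambda: DEFAULT_HIERARCHY)
    similarity_threshold: float = chem.DEFAULT_SIMILARITY_THRESHOLD


# ----------------------------------------------------------------- helpers


def _rows(store: GraphStore, source: str, label: str) -> list[dict]:
    return [dict(n.properties) for n in store.nodes_with_label(f"{source}__{label}")]


def _scalar(props: dict, key: str) -> str:
    value = props.get(key, "")
    if isinstance(value, list):
        return value[0] if value else ""
    return str(value)


def _values(props: dict, key: str) -> list[str]:
    value = props.get(key)
    if value is None or value == "":
        return []
    return [str(v) for v in (value if isinstance(value, list) else [value])]


def _frame(rows: list[dict], extra: dict | None = None) -> pd.DataFrame:
    flat = []
    for row in rows:
        out = {}
        for key, value in {**row, **(extra or {})}.items():
            if key == "source":
                continue
            out[key] = "|".join(str(v) for v in value) if isinstance(value, list) else value
        flat.append(out)
    return pd.DataFrame(flat).fillna("")


def ensure_node(
    store: GraphStore,
    labels: tuple[str, ...],
    identifier: str,
    properties: dict,
    source: str,
    tag: dict | None = None,
) -> tuple[str, bool]:
    """Match a merged node by (primary label, identifier) or create it."""
    existing = store.lookup(labels[0], "identifier", identifier)
    if existing:
        update_node(store, existing[0], properties, source, tag or {"id": identifier})
        for label in labels[1:]:
            store.add_label(existing[0], label)
        return existing[0], False
    node_id = store.add_node(labels, {"identifier": identifier, **properties})
    mark_resource(store, node_id, source, tag or {"id": identifier})
    return node_id, True


def ensure_edge_node(
    store: GraphStore,
    label: str,
    identifier: str,
    participants: list[tuple[str, str]],
    properties: dict,
    source: str,
) -> tuple[str, bool]:
    """Match an edge-node by identifier (merging participant edges) or
    reify it with :func:`create_edge_node`."""
    existing = store.lookup(label, "identifier", identifier)
    if existing:
        node_id = existing[0]
        update_node(store, node_id, properties, source, {"id": identifier})
        from .naming import parse_edge_type

        for participant, type_name in participants:
            parsed = parse_edge_type(type_name)
            own = parsed and parsed.src_abbrev == _abbrev(label)
            if own:
                merge_edge(store, node_id, participant, type_name)
            else:
                merge_edge(store, participant, node_id, type_name)
        return node_id, False
    node_id = create_edge_node(
        store, label, participants, {"identifier": identifier, **properties}
    )
    mark_resource(store, node_id, source, {"id": identifier})
    return node_id, True


def _abbrev(label: str) -> str:
    from .naming import DEFAULT_REGISTRY

    return DEFAULT_REGISTRY.abbreviate(label)


def _remove_primary(store: GraphStore, label: str) -> int:
    removed = 0
    for node in list(store.nodes_with_label(label)):
        if node.primary_label == label and "source" not in node.properties:
            store.remove_node(node.node_id)
            removed += 1
    return removed


def _unique(result) -> str | None:
    return result.node_id


# ---------------------------------------------------------------- routines


def routine_renames(store: GraphStore, ctx: MergeContext) -> dict:
    return {"renamed": apply_renames(store)}


def routine_mondo(store: GraphStore, ctx: MergeContext) -> dict:
    rows = [r for r in _rows(store, "mondo", "term")
            if _scalar(r, "is_obsolete") != "true"]
    for row in rows:
        umls = [x.split(":", 1)[1] for x in _values(row, "xrefs")
                if str(x).startswith("UMLS:")]
        if umls:
            row["umls_id"] = umls if len(umls) > 1 else umls[0]
        row["resource"] = ["Mondo"]
        row["mondo_id"] = _scalar(row, "identifier")
        row.pop("is_obsolete", None)
    frame = _frame(rows)
    replaced, removed, created = replace_or_remove_nodes(
        store, "Disease", frame, match_column="xrefs",
        extra_labels=("Phenotype",),
    )
    edges = 0
    for row in _rows(store, "mondo", "is_a"):
        src = store.lookup("Disease", "identifier", _scalar(row, "source_id"))
        dst = store.lookup("Disease", "identifier", _scalar(row, "target_id"))
        if src and dst:
            merge_edge(store, src[0], dst[0], "IS_A_DiaD", source="Mondo")
            edges += 1
    return {"replaced": replaced, "removed": removed, "created": created,
            "is_a_edges": edges}


def routine_disease_ontology(store: GraphStore, ctx: MergeContext) -> dict:
    resolver = Resolver(store, ctx.xref_tables)
    cascade = ctx.cascades["disease_by_doid"]
    mapped: dict[str, str] = {}
    updated = 0
    for row in _rows(store, "disease_ontology", "term"):
        if _scalar(row, "is_obsolete") == "true":
            continue
        ident = _scalar(row, "identifier")
        result = resolver.resolve(
            {"identifier": ident, "doid": ident, "name": _scalar(row, "name")},
            cascade,
        )
        if result.status != "unique":
            continue
        mapped[ident] = result.node_id
        update_node(
            store, result.node_id,
            {"definition": _scalar(row, "definition")},
            "DO", {"id": ident},
        )
        updated += 1
    edges = 0
    for row in _rows(store, "disease_ontology", "is_a"):
        src = mapped.get(_scalar(row, "source_id"))
        dst = mapped.get(_scalar(row, "target_id"))
        if src and dst:
            if merge_edge(store, src, dst, "IS_A_DiaD", source="DO") == "created":
                edges += 1
    return {"updated": updated, "is_a_created": edges}


def routine_entrez(store: GraphStore, ctx: MergeContext) -> dict:
    rows = _rows(store, "entrez", "gene")
    for row in rows:
        row["resource"] = ["Entrez"]
        row["entrez_id"] = _scalar(row, "identifier")
    replaced, removed, created = replace_or_remove_nodes(
        store, "Gene", _frame(rows), match_column="identifier"
    )
    return {"replaced": replaced, "removed": removed, "created": created}


def routine_omim(store: GraphStore, ctx: MergeContext) -> dict:
    resolver = Resolver(store, ctx.xref_tables)
    mapped: dict[str, tuple[str, bool]] = {}  # mim -> (node_id, is_disease)
    created = updated = 0
    for row in _rows(store, "omim", "entity"):
        ident = _scalar(row, "identifier")
        if _scalar(row, "kind") == "gene":
            result = resolver.resolve(
                {"entrez_id": _scalar(row, "entrez_id")},
                ctx.cascades["gene_by_entrez"],
            )
            if result.status == "unique":
                update_node(store, result.node_id, {}, "OMIM", {"id": ident})
                mapped[ident] = (result.node_id, False)
                updated += 1
            continue
        result = resolver.resolve({"omim_id": ident}, ctx.cascades["disease_by_omim"])
        if result.status == "unique":
            update_node(store, result.node_id, {}, "OMIM", {"id": ident})
            mapped[ident] = (result.node_id, True)
            updated += 1
        else:
            node_id, was_created = ensure_node(
                store, ("Phenotype",), ident,
                {"name": _scalar(row, "name")}, "OMIM",
            )
            mapped[ident] = (node_id, "Disease" in store.nodes[node_id].labels)
            created += int(was_created)
    resolver.invalidate()
    assoc = 0
    for row in _rows(store, "omim", "assoc"):
        pheno = mapped.get(_scalar(row, "phenotype_mim"))
        gene = mapped.get(_scalar(row, "gene_mim"))
        if not pheno or not gene:
            continue
        type_name = "ASSOCIATES_DaG" if pheno[1] else "ASSOCIATES_PaG"
        merge_edge(store, pheno[0], gene[0], type_name, source="OMIM")
        assoc += 1
    return {"updated": updated, "created": created, "assoc_edges": assoc}


_PATHWAY_SOURCES = (("pathway_commons", "PathwayCommons"), ("wikipathways", "WikiPathways"))


def routine_pathways(store: GraphStore, ctx: MergeContext) -> dict:
    removed = _remove_primary(store, "Pathway")
    created = edges = 0
    for source_key, source_name in _PATHWAY_SOURCES:
        for row in _rows(store, source_key, "pathway"):
            ident = _scalar(row, "identifier")
            node_id, was_created = ensure_node(
                store, ("Pathway",), ident,
                {"name": _scalar(row, "name"), "source_db": _scalar(row, "source_db")},
                source_name,
            )
            created += int(was_created)
            for symbol in _values(row, "members"):
                genes = store.lookup("Gene", "name", symbol)
                if len(genes) == 1:
                    merge_edge(
                        store, genes[0], node_id, "PARTICIPATES_IN_GpiPW",
                        source=source_name,
                    )
                    edges += 1
    return {"removed": removed, "created": created, "participates_edges": edges}


def routine_uniprot(store: GraphStore, ctx: MergeContext) -> dict:
    resolver = Resolver(store, ctx.xref_tables)
    created = 0
    for row in _rows(store, "uniprot", "protein"):
        ident = _scalar(row, "identifier")
        _, was_created = ensure_node(
            store, ("Protein",), ident,
            {k: row[k] for k in ("name", "gene_symbol", "entrez_id", "taxon_id",
                                 "synonyms") if k in row},
            "UniProt",
        )
        created += int(was_created)
        gene = resolver.resolve(
            {"entrez_id": _scalar(row, "entrez_id")}, ctx.cascades["gene_by_entrez"]
        )
        if gene.status == "unique":
            protein = store.lookup("Protein", "identifier", ident)[0]
            merge_edge(store, gene.node_id, protein, "PRODUCES_GpP", source="UniProt")
    interactions = 0
    for row in _rows(store, "uniprot", "ppi"):
        a, b = _scalar(row, "protein_a"), _scalar(row, "protein_b")
        pa = store.lookup("Protein", "identifier", a)
        pb = store.lookup("Protein", "identifier", b)
        if not pa or not pb:
            continue
        participants = [
            (pa[0], "INTERACTS_IiP"), (pa[0], "INTERACTS_PiI"),
            (pb[0], "INTERACTS_IiP"), (pb[0], "INTERACTS_PiI"),
        ]
        _, was_created = ensure_edge_node(
            store, "Interaction", f"uniprot:{a}_{b}", participants, {}, "UniProt"
        )
        interactions += int(was_created)
    resolver.invalidate()
    assoc = 0
    for row in _rows(store, "uniprot", "disease_assoc"):
        gene = resolver.resolve(
            {"entrez_id": _scalar(row, "entrez_id"),
             "gene_symbol": _scalar(row, "gene_symbol"),
             "name": _scalar(row, "gene_symbol")},
            ctx.cascades["gene_full"],
        )
        disease = resolver.resolve(
            {"omim_id": _scalar(row, "omim_id")}, ctx.cascades["disease_by_omim"]
        )
        if gene.status == "unique" and disease.status == "unique":
            merge_edge(
                store, disease.node_id, gene.node_id, "ASSOCIATES_DaG",
                {"pubmed_ids": _values(row, "pubmed_ids")}, source="UniProt",
            )
            assoc += 1
    return {"proteins_created": created, "interactions": interactions,
            "disease_assocs": assoc}


def _find_go(store: GraphStore, identifier: str) -> tuple[str, str] | None:
    for label in GO_NAMESPACE_LABELS.values():
        ids = store.lookup(label, "identifier", identifier)
        if ids:
            return label, ids[0]
    return None


def routine_go(store: GraphStore, ctx: MergeContext) -> dict:
    removed = sum(_remove_primary(store, l) for l in GO_NAMESPACE_LABELS.values())
    created = 0
    for row in _rows(store, "go", "term"):
        if _scalar(row, "is_obsolete") == "true":
            continue
        label = GO_NAMESPACE_LABELS.get(_scalar(row, "namespace"))
        if label is None:
            continue
        _, was_created = ensure_node(
            store, (label,), _scalar(row, "identifier"),
            {"name": _scalar(row, "name"), "definition": _scalar(row, "definition")},
            "GO",
        )
        created += int(was_created)
    hierarchy_edges = 0
    for row in _rows(store, "go", "is_a"):
        src = _find_go(store, _scalar(row, "source_id"))
        dst = _find_go(store, _scalar(row, "target_id"))
        if src and dst and src[0] == dst[0]:
            merge_edge(
                store, src[1], dst[1],
                generate_edge_type("IS_A", src[0], dst[0]), source="GO",
            )
            hierarchy_edges += 1
    annotation_edges = 0
    for row in _rows(store, "go", "annotation"):
        relation = GAF_QUALIFIERS.get(_scalar(row, "qualifier"))
        term = _find_go(store, _scalar(row, "go_id"))
        if relation is None or term is None:
            continue
        props = {"evidence": _scalar(row, "evidence"),
                 "pubmed_ids": _values(row, "reference")}
        proteins = store.lookup("Protein", "identifier", _scalar(row, "protein_id"))
        if proteins:
            merge_edge(
                store, proteins[0], term[1],
                generate_edge_type(relation, "Protein", term[0]),
                props, source="GO",
            )
            annotation_edges += 1
        genes = store.lookup("Gene", "name", _scalar(row, "symbol"))
        if len(genes) == 1:
            merge_edge(
                store, genes[0], term[1],
                generate_edge_type(relation, "Gene", term[0]),
                props, source="GO",
            )
            annotation_edges += 1
    return {"removed": removed, "created": created,
            "hierarchy_edges": hierarchy_edges, "annotation_edges": annotation_edges}


def routine_iid(store: GraphStore, ctx: MergeContext) -> dict:
    resolver = Resolver(store, ctx.xref_tables)
    interactions = locations = 0
    for row in _rows(store, "iid", "ppi"):
        a, b = _scalar(row, "protein_a"), _scalar(row, "protein_b")
        pa = store.lookup("Protein", "identifier", a)
        pb = store.lookup("Protein", "identifier", b)
        if not pa or not pb:
            continue
        participants = [
            (pa[0], "INTERACTS_IiP"), (pa[0], "INTERACTS_PiI"),
            (pb[0], "INTERACTS_IiP"), (pb[0], "INTERACTS_PiI"),
        ]
        node_id, was_created = ensure_edge_node(
            store, "Interaction", f"iid:{a}_{b}", participants,
            {"evidence_types": row.get("evidence_types", [])}, "IID",
        )
        interactions += int(was_created)
        cc_name = _scalar(row, "cc_name")
        if cc_name:
            cc = resolver.resolve({"name": cc_name}, ctx.cascades["cc_by_name"])
            if cc.status == "unique":
                merge_edge(
                    store, node_id, cc.node_id,
                    "MIGHT_SUBCELLULAR_LOCATES_ImslCC", source="IID",
                )
                locations += 1
    return {"interactions": interactions, "subcellular_edges": locations}


def _reactome_keep(props: dict) -> bool:
    return (
        _scalar(props, "species") == "Homo sapiens"
        and bool(_values(props, "pubmed_ids"))
    )


def routine_reactome(store: GraphStore, ctx: MergeContext) -> dict:
    resolver = Resolver(store, ctx.xref_tables)
    mapping: dict[str, tuple[str, str]] = {}  # source node id -> (kind, merged id)
    pathways_updated = pathways_created = rle_created = 0
    for node in store.nodes_with_label("reactome__Pathway"):
        ident = _scalar(node.properties, "identifier")
        result = resolver.resolve(
            {"reactome_id": ident, "name": _scalar(node.properties, "name")},
            ctx.cascades["pathway_reactome"],
        )
        if result.status == "unique":
            update_node(store, result.node_id, {}, "Reactome", {"id": ident})
            mapping[node.node_id] = ("Pathway", result.node_id)
            pathways_updated += 1
        else:
            merged, was_created = ensure_node(
                store, ("Pathway",), ident,
                {"name": _scalar(node.properties, "name")}, "Reactome",
            )
            mapping[node.node_id] = ("Pathway", merged)
            pathways_created += int(was_created)
        resolver.invalidate()
    for label in RLE_LABELS:
        for node in store.nodes_with_label(f"reactome__{label}"):
            if not _reactome_keep(node.properties):
                continue
            props = {
                k: v for k, v in node.properties.items()
                if k not in ("identifier", "source")
            }
            merged, was_created = ensure_node(
                store, (label, "ReactionLikeEvent"),
                _scalar(node.properties, "identifier"), props, "Reactome",
            )
            mapping[node.node_id] = ("ReactionLikeEvent", merged)
            rle_created += int(was_created)
    resolver.invalidate()
    edges = 0
    for edge_id in sorted(store.edges):
        edge = store.edges[edge_id]
        if not edge.type_name.startswith("reactome__"):
            continue
        raw = edge.type_name.removeprefix("reactome__")
        src = mapping.get(edge.source_id)
        if src is None:
            continue
        if raw in ("precedingEvent", "hasEvent"):
            dst = mapping.get(edge.target_id)
            if dst is None:
                continue
            if raw == "precedingEvent":
                type_name = generate_edge_type("PRECEDING_REACTION", src[0], dst[0])
            elif (src[0], dst[0]) == ("Pathway", "ReactionLikeEvent"):
                type_name = "PARTICIPATES_IN_PWpiRLE"
            else:
                type_name = "HAS_ENCAPSULATED_EVENT_PWheePW"
            merge_edge(store, src[1], dst[1], type_name, source="Reactome")
            edges += 1
        elif raw == "compartment":
            ref = store.nodes[edge.target_id]
            cc = _find_go(store, _scalar(ref.properties, "go_id"))
            if cc is None:
                continue
            merge_edge(
                store, src[1], cc[1],
                generate_edge_type("IN_COMPARTMENT", src[0], cc[0]),
                source="Reactome",
            )
            edges += 1
        elif raw == "disease":
            ref = store.nodes[edge.target_id]
            disease = resolver.resolve(
                {"doid": _scalar(ref.properties, "doid")},
                ctx.cascades["disease_by_doid"],
            )
            if disease.status != "unique":
                continue
            type_name = (
                "LEADS_TO_DISEASE_RLEltdD" if src[0] == "ReactionLikeEvent"
                else "LEADS_TO_PWltD"
            )
            merge_edge(store, src[1], disease.node_id, type_name, source="Reactome")
            edges += 1
    return {"pathways_updated": pathways_updated,
            "pathways_created": pathways_created,
            "events_created": rle_created, "edges": edges}


def routine_clinvar(store: GraphStore, ctx: MergeContext) -> dict:
    rows = _rows(store, "clinvar", "variant")
    created = 0
    for row in rows:
        kind = _scalar(row, "kind")
        if kind not in ("GeneVariant", "Haplotype", "Genotype"):
            continue
        props = {"name": _scalar(row, "name")}
        if _scalar(row, "rs_id"):
            props["rs_id"] = _scalar(row, "rs_id")
        if _scalar(row, "trait"):
            props["trait"] = _scalar(row, "trait")
        _, was_created = ensure_node(
            store, (kind, "Variant"), _scalar(row, "identifier"), props, "ClinVar"
        )
        created += int(was_created)
    edges = 0
    for row in rows:
        ident = _scalar(row, "identifier")
        me = store.lookup("Variant", "identifier", ident)
        if not me:
            continue
        gene_id = _scalar(row, "gene_id")
        if gene_id:
            genes = store.lookup("Gene", "identifier", gene_id)
            if genes:
                merge_edge(store, genes[0], me[0], "HAS_GhV", source="ClinVar")
                edges += 1
        for column, type_name in (
            ("member_variant", "HAS_HhGV"),
            ("haplotype", "HAS_GThH"),
            ("variant", "HAS_GThGV"),
        ):
            ref = _scalar(row, column)
            if ref:
                others = store.lookup("Variant", "identifier", ref)
                if others:
                    merge_edge(store, me[0], others[0], type_name, source="ClinVar")
                    edges += 1
    return {"variants_created": created, "edges": edges}


def routine_drugbank(store: GraphStore, ctx: MergeContext) -> dict:
    resolver = Resolver(store, ctx.xref_tables)
    rows = _rows(store, "drugbank", "drug")
    for row in rows:
        row["resource"] = ["DrugBank"]
        row["drugbank_id"] = _scalar(row, "identifier")
    replaced, removed, created = replace_or_remove_nodes(
        store, "Compound", _frame(rows), match_column="identifier"
    )
    for row in _rows(store, "drugbank", "salt"):
        salt, _ = ensure_node(
            store, ("Salt", "Compound", "Chemical"), _scalar(row, "identifier"),
            {"name": _scalar(row, "name")}, "DrugBank",
        )
        parents = store.lookup("Compound", "identifier", _scalar(row, "parent"))
        if parents:
            merge_edge(store, parents[0], salt, "PART_OF_CpoSA", source="DrugBank")
    for row in _rows(store, "drugbank", "product"):
        product, _ = ensure_node(
            store, ("Product",), _scalar(row, "identifier"),
            {"name": _scalar(row, "name")}, "DrugBank",
        )
        drugs = store.lookup("Compound", "identifier", _scalar(row, "drug"))
        if drugs:
            merge_edge(store, drugs[0], product, "HAS_ChPR", source="DrugBank")
    for row in _rows(store, "drugbank", "interaction"):
        a = store.lookup("Compound", "identifier", _scalar(row, "drug_a"))
        b = store.lookup("Compound", "identifier", _scalar(row, "drug_b"))
        if a and b:
            merge_edge(store, a[0], b[0], "INTERACTS_CiC", source="DrugBank")
    resolver.invalidate()
    adr_edges = 0
    for row in _rows(store, "drugbank", "adr"):
        rs = _scalar(row, "rs_id")
        drug = store.lookup("Compound", "identifier", _scalar(row, "drug_id"))
        if not rs or not drug:
            continue
        result = resolver.resolve({"rs_id": rs}, ctx.cascades["variant_by_rs"])
        if result.status == "unique":
            variant = result.node_id
        elif result.status == "unmatched":
            variant, _ = ensure_node(
                store, ("GeneVariant", "Variant"), rs, {"rs_id": rs}, "DrugBank"
            )
            resolver.invalidate()
        else:
            logger.warning("ambiguous rs-identifier %s; skipping ADR row", rs)
            continue
        merge_edge(store, variant, drug[0], "COMBINATION_CAUSES_ADR_VccaCH",
                   source="DrugBank")
        adr_edges += 1
    # recompute structure-similarity edges from scratch
    for edge in list(store.edges_of_type(chem.RESEMBLES_TYPE)):
        store.remove_edge(edge.edge_id)
    compounds = []
    for node in store.nodes_with_label("Compound"):
        smiles = node.properties.get("smiles")
        if isinstance(smiles, str) and smiles:
            compounds.append((node.identifier, smiles))
    similarity = chem.resemblance_edges(
        compounds, threshold=ctx.similarity_threshold
    )
    for edge in similarity:
        src = store.lookup("Compound", "identifier", edge["source"])
        dst = store.lookup("Compound", "identifier", edge["target"])
        props = {k: v for k, v in edge.items() if k not in ("source", "target")}
        store.add_edge(chem.RESEMBLES_TYPE, src[0], dst[0], props)
    return {"replaced": replaced, "removed": removed, "created": created,
            "adr_edges": adr_edges, "resemblance_edges": len(similarity)}


def routine_hpo(store: GraphStore, ctx: MergeContext) -> dict:
    resolver = Resolver(store, ctx.xref_tables)
    mapped: dict[str, str] = {}
    created = updated = 0
    for row in _rows(store, "hpo", "term"):
        ident = _scalar(row, "identifier")
        entity = {
            "mesh_id": _scalar(row, "mesh_id"),
            "umls_id": _scalar(row, "umls_id"),
            "name": _scalar(row, "name"),
        }
        result = resolver.resolve(entity, ctx.cascades["symptom"])
        if result.status == "unique":
            update_node(
                store, result.node_id,
                {"umls_id": _scalar(row, "umls_id")} if _scalar(row, "umls_id") else {},
                "HPO", {"id": ident},
            )
            mapped[ident] = result.node_id
            updated += 1
        else:
            props = {"name": _scalar(row, "name")}
            if _scalar(row, "umls_id"):
                props["umls_id"] = _scalar(row, "umls_id")
            node_id, was_created = ensure_node(
                store, ("Symptom", "Phenotype"), ident, props, "HPO"
            )
            mapped[ident] = node_id
            created += int(was_created)
            resolver.invalidate()
    resolver.invalidate()
    presents = 0
    for row in _rows(store, "hpo", "annotation"):
        disease_id = _scalar(row, "disease_id")
        entity = (
            {"omim_id": disease_id} if disease_id.startswith("OMIM")
            else {"orpha_id": disease_id}
        )
        disease = resolver.resolve(entity, ctx.cascades["disease_full"])
        symptom = mapped.get(_scalar(row, "hp_id"))
        if disease.status == "unique" and symptom:
            merge_edge(store, disease.node_id, symptom, "PRESENTS_DpS", source="HPO")
            presents += 1
    return {"symptoms_updated": updated, "symptoms_created": created,
            "presents_edges": presents}


def routine_ctd(store: GraphStore, ctx: MergeContext) -> dict:
    resolver = Resolver(store, ctx.xref_tables)
    mapped: dict[str, str] = {}
    matched = created = 0
    for row in _rows(store, "ctd", "chemical"):
        ident = _scalar(row, "identifier")
        entity = {
            "cas": _scalar(row, "cas"), "inchikey": _scalar(row, "inchikey"),
            "mesh_id": ident, "name": _scalar(row, "name"),
        }
        result = resolver.resolve(entity, ctx.cascades["chemical_ctd"])
        if result.status == "unique":
            update_node(store, result.node_id, {}, "CTD", {"id": ident})
            mapped[ident] = result.node_id
            matched += 1
        elif result.status == "unmatched":
            node_id, was_created = ensure_node(
                store, ("Chemical",), ident, {"name": _scalar(row, "name")}, "CTD"
            )
            mapped[ident] = node_id
            created += int(was_created)
            resolver.invalidate()
    apply_label_hierarchy(store, ctx.hierarchy)
    resolver.invalidate()
    edges = 0

    def chem_node(cid: str) -> str | None:
        return mapped.get(cid)

    for row in _rows(store, "ctd", "chem_gene"):
        chem_id = chem_node(_scalar(row, "chemical_id"))
        genes = store.lookup("Gene", "identifier", _scalar(row, "gene_id"))
        relation = RELATION_TOKENS.get(_scalar(row, "relation"))
        if not chem_id or not genes or not relation:
            continue
        props = {"pubmed_ids": _values(row, "pubmed_ids")}
        if _scalar(row, "target_type") == "protein":
            proteins = [
                e.target_id for e in store.out_edges(genes[0])
                if e.type_name == "PRODUCES_GpP"
            ]
            if not proteins:
                continue
            merge_edge(
                store, chem_id, proteins[0],
                generate_edge_type(relation, "Chemical", "Protein"),
                props, source="CTD",
            )
        else:
            merge_edge(
                store, chem_id, genes[0],
                generate_edge_type(relation, "Chemical", "Gene"),
                props, source="CTD",
            )
        edges += 1
    for row in _rows(store, "ctd", "chem_disease"):
        chem_id = chem_node(_scalar(row, "chemical_id"))
        disease = resolver.resolve(
            {"doid": _scalar(row, "disease_id")}, ctx.cascades["disease_full"]
        )
        if not chem_id or disease.status != "unique":
            continue
        relation = (
            "TREATS" if _scalar(row, "DirectEvidence") == "therapeutic" else "INDUCES"
        )
        merge_edge(
            store, chem_id, disease.node_id,
            generate_edge_type(relation, "Chemical", "Disease"),
            {"pubmed_ids": _values(row, "pubmed_ids"),
             "direct_evidence": _scalar(row, "DirectEvidence")},
            source="CTD",
        )
        edges += 1
    for row in _rows(store, "ctd", "gene_disease"):
        genes = store.lookup("Gene", "identifier", _scalar(row, "gene_id"))
        disease = resolver.resolve(
            {"doid": _scalar(row, "disease_id")}, ctx.cascades["disease_full"]
        )
        if not genes or disease.status != "unique":
            continue
        merge_edge(
            store, disease.node_id, genes[0], "ASSOCIATES_DaG",
            {"pubmed_ids": _values(row, "pubmed_ids")}, source="CTD",
        )
        edges += 1
    for row in _rows(store, "ctd", "chem_go"):
        chem_id = chem_node(_scalar(row, "chemical_id"))
        term = _find_go(store, _scalar(row, "go_id"))
        relation = RELATION_TOKENS.get(_scalar(row, "relation"))
        if not chem_id or term is None or not relation:
            continue
        merge_edge(
            store, chem_id, term[1],
            generate_edge_type(relation, "Chemical", term[0]), source="CTD",
        )
        edges += 1
    for row in _rows(store, "ctd", "pathway_gene"):
        pathway = resolver.resolve(
            {"reactome_id": _scalar(row, "pathway_id")},
            ctx.cascades["pathway_reactome"],
        )
        genes = store.lookup("Gene", "identifier", _scalar(row, "gene_id"))
        if pathway.status == "unique" and genes:
            merge_edge(
                store, genes[0], pathway.node_id, "PARTICIPATES_IN_GpiPW",
                source="CTD",
            )
            edges += 1
    return {"chemicals_matched": matched, "chemicals_created": created,
            "edges": edges}


def routine_ndfrt(store: GraphStore, ctx: MergeContext) -> dict:
    removed = _remove_primary(store, "PharmacologicalClass")
    resolver = Resolver(store, ctx.xref_tables)
    rows = _rows(store, "ndfrt", "class")
    for row in rows:
        ensure_node(
            store, ("PharmacologicalClass",), _scalar(row, "identifier"),
            {"name": _scalar(row, "name"), "kind": _scalar(row, "kind")}, "NDFRT",
        )
    hierarchy_edges = 0
    for row in rows:
        parent = _scalar(row, "parent")
        if parent:
            parents = store.lookup("PharmacologicalClass", "identifier", parent)
            child = store.lookup(
                "PharmacologicalClass", "identifier", _scalar(row, "identifier")
            )
            if parents and child:
                merge_edge(store, parents[0], child[0], "INCLUDES_PCiPC",
                           source="NDFRT")
                hierarchy_edges += 1
    resolver.invalidate()

    def resolve_endpoint(kind: str, ref: str):
        if kind == "class":
            ids = store.lookup("PharmacologicalClass", "identifier", ref)
            return ("PharmacologicalClass", ids[0]) if ids else None
        if kind == "chemical":
            result = resolver.resolve({"name": ref}, ctx.cascades["chemical_by_name"])
            return ("Chemical", result.node_id) if result.status == "unique" else None
        if kind == "disease":
            entity = {"umls_id": ref} if ref.startswith("C") else {"name": ref}
            result = resolver.resolve(entity, ctx.cascades["disease_full"])
            return ("Disease", result.node_id) if result.status == "unique" else None
        return None

    edges = 0
    for row in _rows(store, "ndfrt", "relation"):
        subject = resolve_endpoint(_scalar(row, "subject_kind"),
                                   _scalar(row, "subject_ref"))
        obj = resolve_endpoint(_scalar(row, "object_kind"),
                               _scalar(row, "object_ref"))
        if subject is None or obj is None:
            continue
        merge_edge(
            store, subject[1], obj[1],
            generate_edge_type(_scalar(row, "relation"), subject[0], obj[0]),
            source="NDFRT",
        )
        edges += 1
    return {"classes_removed": removed, "classes": len(rows),
            "hierarchy_edges": hierarchy_edges, "edges": edges}


def routine_reactome_chemicals(store: GraphStore, ctx: MergeContext) -> dict:
    resolver = Resolver(store, ctx.xref_tables)
    treatments = io_edges = 0
    for row in _rows(store, "reactome", "Treatment"):
        chemical = resolver.resolve(
            {"name": _scalar(row, "chemical_name")}, ctx.cascades["chemical_by_name"]
        )
        disease = resolver.resolve(
            {"doid": _scalar(row, "doid")}, ctx.cascades["disease_by_doid"]
        )
        cc = _find_go(store, _scalar(row, "go_id"))
        if chemical.status != "unique" or disease.status != "unique" or cc is None:
            continue
        participants = [
            (chemical.node_id, "TREATS_CHtT"),
            (disease.node_id, "TREATS_TtD"),
            (cc[1], "IS_LOCALIZED_IN_TiliCC"),
        ]
        _, was_created = ensure_edge_node(
            store, "Treatment", _scalar(row, "identifier"), participants, {},
            "Reactome",
        )
        treatments += int(was_created)
    for label in RLE_LABELS:
        for row in _rows(store, "reactome", label):
            if not _reactome_keep(row):
                continue
            rles = store.lookup(
                "ReactionLikeEvent", "identifier", _scalar(row, "identifier")
            )
            if not rles:
                continue
            for column, type_name, rle_is_source in (
                ("input_chemical", "HAS_INPUT_RLEhiCH", True),
                ("output_chemical", "HAS_OUTPUT_RLEhoCH", True),
            ):
                name = _scalar(row, column)
                if not name:
                    continue
                chemical = resolver.resolve(
                    {"name": name}, ctx.cascades["chemical_by_name"]
                )
                if chemical.status == "unique":
                    merge_edge(store, rles[0], chemical.node_id, type_name,
                               source="Reactome")
                    io_edges += 1
            protein_ref = _scalar(row, "protein_input")
            if protein_ref:
                proteins = store.lookup("Protein", "identifier", protein_ref)
                if proteins:
                    merge_edge(store, proteins[0], rles[0], "IS_INPUT_OF_PiioRLE",
                               source="Reactome")
                    io_edges += 1
    return {"treatments": treatments, "io_edges": io_edges}


def routine_clinvar_chemicals(store: GraphStore, ctx: MergeContext) -> dict:
    resolver = Resolver(store, ctx.xref_tables)
    edges = 0
    for row in _rows(store, "clinvar", "drug_assoc"):
        variants = store.lookup("Variant", "identifier", _scalar(row, "variant_id"))
        chemical = resolver.resolve(
            {"name": _scalar(row, "drug_name")}, ctx.cascades["chemical_by_name"]
        )
        relation = VARIANT_ASSOC_TOKENS.get(_scalar(row, "association_type"))
        if not variants or chemical.status != "unique" or relation is None:
            continue
        merge_edge(
            store, variants[0], chemical.node_id,
            generate_edge_type(relation, "Variant", "Chemical"), source="ClinVar",
        )
        edges += 1
    return {"association_edges": edges}


def routine_drugbank_remainder(store: GraphStore, ctx: MergeContext) -> dict:
    classes = class_edges = target_edges = 0
    for row in _rows(store, "drugbank", "atc"):
        code, parent_code = _scalar(row, "code"), _scalar(row, "parent_code")
        child, was_created = ensure_node(
            store, ("PharmacologicalClass",), f"atc:{code}",
            {"name": _scalar(row, "name")}, "DrugBank",
        )
        classes += int(was_created)
        if parent_code:
            parent, was_created = ensure_node(
                store, ("PharmacologicalClass",), f"atc:{parent_code}",
                {"name": _scalar(row, "parent_name")}, "DrugBank",
            )
            classes += int(was_created)
            merge_edge(store, child, parent, "BELONGS_TO_PCbtPC", source="DrugBank")
            class_edges += 1
    for node in store.nodes_with_label("Compound"):
        for code in _values(node.properties, "atc_codes"):
            class_code = code[:-2] if len(code) > 2 else code
            classes_found = store.lookup(
                "PharmacologicalClass", "identifier", f"atc:{class_code}"
            )
            if classes_found:
                merge_edge(store, node.node_id, classes_found[0],
                           "BELONGS_TO_CHbtPC", source="DrugBank")
                class_edges += 1
    category_labels = {"target": "Target", "enzyme": "Enzyme",
                       "carrier": "Carrier", "transporter": "Transporter"}
    for row in _rows(store, "drugbank", "target"):
        proteins = store.lookup("Protein", "identifier", _scalar(row, "uniprot_id"))
        drugs = store.lookup("Compound", "identifier", _scalar(row, "drug_id"))
        relation = RELATION_TOKENS.get(_scalar(row, "action"))
        if not proteins or not drugs or not relation:
            continue
        extra_label = category_labels.get(_scalar(row, "category"))
        if extra_label:
            store.add_label(proteins[0], extra_label)
        merge_edge(
            store, drugs[0], proteins[0],
            generate_edge_type(relation, "Chemical", "Protein"),
            {"pubmed_ids": _values(row, "pubmed_ids")}, source="DrugBank",
        )
        target_edges += 1
    return {"atc_classes": classes, "class_edges": class_edges,
            "target_edges": target_edges}


def routine_sider(store: GraphStore, ctx: MergeContext) -> dict:
    removed = _remove_primary(store, "SideEffect")
    resolver = Resolver(store, ctx.xref_tables)
    created = 0
    for row in _rows(store, "sider", "side_effect"):
        ident = _scalar(row, "identifier")
        _, was_created = ensure_node(
            store, ("SideEffect", "Phenotype"), ident,
            {"name": _scalar(row, "name"), "umls_id": ident}, "SIDER",
        )
        created += int(was_created)
    resolver.invalidate()
    causes = 0
    for row in _rows(store, "sider", "causes"):
        chemical = resolver.resolve(
            {"name": _scalar(row, "drug_name")}, ctx.cascades["chemical_by_name"]
        )
        ses = store.lookup("SideEffect", "identifier", _scalar(row, "se_id"))
        if chemical.status != "unique" or not ses:
            logger.warning("skipping side-effect row %s", dict(row))
            continue
        merge_edge(store, chemical.node_id, ses[0], "CAUSES_CHcSE", source="SIDER")
        causes += 1
    return {"removed": removed, "created": created, "causes_edges": causes}


def routine_aeolus(store: GraphStore, ctx: MergeContext) -> dict:
    resolver = Resolver(store, ctx.xref_tables)
    outcome_nodes: dict[str, tuple[str, str]] = {}  # outcome id -> (kind, node id)
    matched = created = 0
    for row in _rows(store, "aeolus", "outcome"):
        ident = _scalar(row, "identifier")
        entity = {
            "meddra_id": _scalar(row, "meddra_id"),
            "umls_id": ident,
            "name": _scalar(row, "name"),
        }
        if _scalar(row, "kind") == "disease":
            result = resolver.resolve(entity, ctx.cascades["disease_by_umls"])
            if result.status == "unique":
                outcome_nodes[ident] = ("disease", result.node_id)
                update_node(store, result.node_id, {}, "AEOLUS", {"id": ident})
                matched += 1
            continue
        result = resolver.resolve(entity, ctx.cascades["sideeffect"])
        if result.status == "unique":
            update_node(store, result.node_id, {}, "AEOLUS", {"id": ident})
            outcome_nodes[ident] = ("se", result.node_id)
            matched += 1
        else:
            node_id, was_created = ensure_node(
                store, ("SideEffect", "Phenotype"), ident,
                {"name": _scalar(row, "name"), "umls_id": ident}, "AEOLUS",
            )
            outcome_nodes[ident] = ("se", node_id)
            created += int(was_created)
            resolver.invalidate()
    resolver.invalidate()
    edges = 0
    for row in _rows(store, "aeolus", "pair"):
        outcome = outcome_nodes.get(_scalar(row, "outcome_id"))
        chemical = resolver.resolve(
            {"name": _scalar(row, "drug_name")}, ctx.cascades["chemical_by_name"]
        )
        if outcome is None or chemical.status != "unique":
            continue
        kind, node_id = outcome
        type_name = "MIGHT_INDUCES_CHmiD" if kind == "disease" else "MIGHT_CAUSES_CHmcSE"
        merge_edge(
            store, chemical.node_id, node_id, type_name,
            {"frequency": _scalar(row, "frequency"),
             "report_count": _scalar(row, "report_count")},
            source="AEOLUS",
        )
        edges += 1
    return {"outcomes_matched": matched, "outcomes_created": created,
            "pair_edges": edges}


def _pharmgkb_entity_map(store: GraphStore, ctx: MergeContext) -> dict[str, str | None]:
    """Resolve every PharmGKB source entity to a merged node (or None)."""
    resolver = Resolver(store, ctx.xref_tables)
    mapping: dict[str, str | None] = {}
    for node in store.nodes_with_label("pharmgkb__Chemical"):
        result = resolver.resolve(
            {"drugbank_id": _scalar(node.properties, "drugbank_id"),
             "name": _scalar(node.properties, "name")},
            ctx.cascades["chemical_pgkb"],
        )
        mapping[_scalar(node.properties, "identifier")] = result.node_id
    for node in store.nodes_with_label("pharmgkb__Gene"):
        result = resolver.resolve(
            {"entrez_id": _scalar(node.properties, "entrez_id"),
             "gene_symbol": _scalar(node.properties, "name"),
             "name": _scalar(node.properties, "name")},
            ctx.cascades["gene_full"],
        )
        mapping[_scalar(node.properties, "identifier")] = result.node_id
    for node in store.nodes_with_label("pharmgkb__Phenotype"):
        entity = {"umls_id": _scalar(node.properties, "umls_id"),
                  "name": _scalar(node.properties, "name")}
        found = None
        for cascade_name in ("disease_by_umls", "symptom", "sideeffect"):
            result = resolver.resolve(entity, ctx.cascades[cascade_name])
            if result.status == "unique":
                found = result.node_id
                break
        mapping[_scalar(node.properties, "identifier")] = found
    for node in store.nodes_with_label("pharmgkb__Variant"):
        result = resolver.resolve(
            {"rs_id": _scalar(node.properties, "rs_id")},
            ctx.cascades["variant_by_rs"],
        )
        mapping[_scalar(node.properties, "identifier")] = result.node_id
    return mapping


def routine_pharmgkb_entities(store: GraphStore, ctx: MergeContext) -> dict:
    mapping = _pharmgkb_entity_map(store, ctx)
    updated = created = 0
    for node in store.nodes_with_label("pharmgkb__Chemical"):
        ident = _scalar(node.properties, "identifier")
        if mapping.get(ident):
            update_node(store, mapping[ident], {}, "PharmGKB", {"id": ident})
            updated += 1
    for node in store.nodes_with_label("pharmgkb__Gene"):
        ident = _scalar(node.properties, "identifier")
        if mapping.get(ident):
            update_node(store, mapping[ident], {}, "PharmGKB", {"id": ident})
            updated += 1
    for node in store.nodes_with_label("pharmgkb__Phenotype"):
        ident = _scalar(node.properties, "identifier")
        if mapping.get(ident):
            update_node(store, mapping[ident], {}, "PharmGKB", {"id": ident})
            updated += 1
        else:
            node_id, was_created = ensure_node(
                store, ("Phenotype",), ident,
                {"name": _scalar(node.properties, "name")}, "PharmGKB",
            )
            mapping[ident] = node_id
            created += int(was_created)
    for node in store.nodes_with_label("pharmgkb__Variant"):
        ident = _scalar(node.properties, "identifier")
        rs = _scalar(node.properties, "rs_id")
        if mapping.get(ident):
            update_node(store, mapping[ident], {}, "PharmGKB", {"id": ident})
            updated += 1
        elif rs:
            node_id, was_created = ensure_node(
                store, ("GeneVariant", "Variant"), rs,
                {"rs_id": rs, "name": _scalar(node.properties, "name")}, "PharmGKB",
            )
            mapping[ident] = node_id
            created += int(was_created)
    return {"updated": updated, "created": created}


def routine_dbsnp(store: GraphStore, ctx: MergeContext) -> dict:
    resolver = Resolver(store, ctx.xref_tables)
    stub_rows = _rows(store, "dbsnp", "rs")
    valid_rs = {_scalar(r, "rs_id") for r in stub_rows}
    updated = 0
    for row in stub_rows:
        rs = _scalar(row, "rs_id")
        result = resolver.resolve({"rs_id": rs}, ctx.cascades["variant_by_rs"])
        if result.status == "unique":
            update_node(store, result.node_id, {}, "dbSNP", {"id": rs})
            updated += 1
    pruned = 0
    for node in list(store.nodes_with_label("GeneVariant")):
        if "source" in node.properties:
            continue
        rs_values = _values(node.properties, "rs_id")
        if rs_values and not any(rs in valid_rs for rs in rs_values):
            store.remove_node(node.node_id)
            pruned += 1
    resolver.invalidate()
    has_edges = 0
    for row in stub_rows:
        gene_id = _scalar(row, "gene_id")
        if not gene_id:
            continue
        result = resolver.resolve(
            {"rs_id": _scalar(row, "rs_id")}, ctx.cascades["variant_by_rs"]
        )
        genes = store.lookup("Gene", "identifier", gene_id)
        if result.status == "unique" and genes:
            if merge_edge(store, genes[0], result.node_id, "HAS_GhV",
                          source="dbSNP") == "created":
                has_edges += 1
    return {"updated": updated, "pruned": pruned, "has_edges_created": has_edges}


_CA_PRIORITY = ("Gene", "Variant", "Chemical", "PharmacologicalClass", "Phenotype")
_VA_PRIORITY = ("Gene", "Haplotype", "Variant", "Chemical", "PharmacologicalClass",
                "Phenotype")


def _annotation_target_label(labels: tuple[str, ...], priority) -> str | None:
    for label in priority:
        if label in labels:
            return label
    return None


def routine_pharmgkb_edges(store: GraphStore, ctx: MergeContext) -> dict:
    mapping = _pharmgkb_entity_map(store, ctx)
    source_by_id: dict[str, str] = {}
    for label in ("pharmgkb__ClinicalAnnotation", "pharmgkb__VariantAnnotation",
                  "pharmgkb__Chemical", "pharmgkb__Gene", "pharmgkb__Phenotype",
                  "pharmgkb__Variant"):
        for node in store.nodes_with_label(label):
            source_by_id[node.node_id] = _scalar(node.properties, "identifier")

    kept: dict[str, str] = {}  # source annotation identifier -> merged label
    annotations = 0
    for label, merged_label, priority in (
        ("pharmgkb__ClinicalAnnotation", "ClinicalAnnotation", _CA_PRIORITY),
        ("pharmgkb__VariantAnnotation", "VariantAnnotation", _VA_PRIORITY),
    ):
        for node in store.nodes_with_label(label):
            props = node.properties
            level = _scalar(props, "evidence_level")
            significance = _scalar(props, "significance")
            if merged_label == "ClinicalAnnotation" and level not in ("1", "2", "3"):
                continue
            if merged_label == "VariantAnnotation" and significance.lower() != "yes":
                continue
            ident = _scalar(props, "identifier")
            participants: list[tuple[str, str]] = []
            for edge in store.out_edges(node.node_id):
                if edge.type_name != "pharmgkb__associates":
                    continue
                target = mapping.get(source_by_id.get(edge.target_id, ""))
                if not target:
                    continue
                target_label = _annotation_target_label(
                    store.nodes[target].labels, priority
                )
                if target_label is None:
                    continue
                participants.append(
                    (target,
                     generate_edge_type("ASSOCIATES", merged_label, target_label))
                )
            if len(participants) < 2:
                continue
            extra = {"evidence_level": level} if level else {"significance": significance}
            _, was_created = ensure_edge_node(
                store, merged_label, ident, participants, extra, "PharmGKB"
            )
            kept[ident] = merged_label
            annotations += int(was_created)

    evidence_edges = has_edges = 0
    for edge_id in sorted(store.edges):
        edge = store.edges[edge_id]
        if edge.type_name == "pharmgkb__evidence":
            ca = source_by_id.get(edge.source_id, "")
            va = source_by_id.get(edge.target_id, "")
            if kept.get(ca) == "ClinicalAnnotation" and kept.get(va) == "VariantAnnotation":
                ca_node = store.lookup("ClinicalAnnotation", "identifier", ca)
                va_node = store.lookup("VariantAnnotation", "identifier", va)
                merge_edge(store, ca_node[0], va_node[0], "HAS_EVIDENCE_CAheVA",
                           source="PharmGKB")
                evidence_edges += 1
        elif edge.type_name == "pharmgkb__has_variant":
            gene = mapping.get(source_by_id.get(edge.source_id, ""))
            variant = mapping.get(source_by_id.get(edge.target_id, ""))
            if gene and variant:
                merge_edge(store, gene, variant, "HAS_GhV", source="PharmGKB")
                has_edges += 1
    return {"annotations": annotations, "evidence_edges": evidence_edges,
            "has_edges": has_edges}


def routine_equal_allele(store: GraphStore, ctx: MergeContext) -> dict:
    labels_added = apply_label_hierarchy(store, ctx.hierarchy)
    equal = generate_equal_edges(store)
    allele = generate_allele_edges(store)
    return {"labels_added": labels_added, "equal_edges": equal,
            "allele_edges": allele}


#: routine name -> callable, in default plan order.
ROUTINES = {
    "renames": routine_renames,
    "mondo": routine_mondo,
    "disease_ontology": routine_disease_ontology,
    "entrez": routine_entrez,
    "omim": routine_omim,
    "pathways": routine_pathways,
    "uniprot": routine_uniprot,
    "go": routine_go,
    "iid": routine_iid,
    "reactome": routine_reactome,
    "clinvar": routine_clinvar,
    "drugbank": routine_drugbank,
    "hpo": routine_hpo,
    "ctd": routine_ctd,
    "ndfrt": routine_ndfrt,
    "reactome_chemicals": routine_reactome_chemicals,
    "clinvar_chemicals": routine_clinvar_chemicals,
    "drugbank_remainder": routine_drugbank_remainder,
    "sider": routine_sider,
    "aeolus": routine_aeolus,
    "pharmgkb_entities": routine_pharmgkb_entities,
    "dbsnp": routine_dbsnp,
    "pharmgkb_edges": routine_pharmgkb_edges,
    "equal_allele": routine_equal_allele,
}
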