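"""End-to-end orchestration: prepare -> integrate -> merge -> extract.

``prepare_corpus`` runs every bundled source adapter (parsing plus the
catalogue filters) and the per-source preparation steps that combine
inputs across sources (release unification, identifier reconciliation,
gene-set membership filtering, evidence-code translation).
``integrate_corpus`` loads all prepared tables and graphs into one store
as disconnected source subgraphs (labels prefixed ``<source>__`` and a
``source`` marker property), alongside the seed hetnet.  ``run_pipeline``
chains both with the merge plan and the final extraction.
"""

from __future__ import annotations

import logging
from importlib import resources as _resources
from pathlib import Path

import pandas as pd
import yaml

from . import adapters, graphml
from .adapters import (
    bundled_adapter_registry,
    dedupe_entities,
    filter_in_identifier_list,
    filter_source_whitelist,
    translate_evidence_code,
)
from .errors import ConfigurationError
from .graph import GraphStore, load_node_table
from .merge import MergePlan, run_merge
from .resolver import XrefTable
from .routines import ROUTINES, MergeContext
from .validate import (
    check_human_only,
    extract_merged_subgraph,
    validate_edge_names,
    validate_resource_tags,
)

logger = logging.getLogger(__name__)

LIST = "|"


def load_merge_plan(path: Path | str | None = None) -> MergePlan:
    """The bundled (or given) merge plan YAML as a MergePlan."""
    if path is None:
        text = _resources.files("kgforge").joinpath("configs/merge_plan.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return MergePlan(tuple((s["source"], s["routine"]) for s in raw["steps"]))


# ------------------------------------------------------------- preparation


def _protein_coding_symbols(prepared: dict) -> set[str]:
    genes = prepared.get("entrez", {}).get("tables", {}).get("gene")
    if genes is None:
        return set()
    coding = genes[genes["type_of_gene"] == "protein-coding"]
    return set(coding["name"].astype(str))


def _filter_members(df: pd.DataFrame, symbols: set[str]) -> pd.DataFrame:
    df = df.copy()
    df["members"] = df["members"].map(
        lambda cell: LIST.join(
            m for m in str(cell).split(LIST) if m in symbols
        )
    )
    return df


def _prepare_pathway_commons(tables: dict, prepared: dict) -> dict:
    raw = tables["raw"].copy()
    parts = raw["description"].str.extract(
        r"name:\s*(?P<name>[^;]+);\s*datasource:\s*(?P<datasource>[^;]+);"
        r"\s*organism:\s*(?P<organism>\S+)"
    )
    raw = pd.concat([raw[["identifier", "members"]], parts], axis=1)
    raw["name"] = raw["name"].str.strip()
    raw["datasource"] = raw["datasource"].str.strip()
    raw = filter_source_whitelist(raw, "datasource")
    raw = raw[raw["organism"] == "9606"].reset_index(drop=True)
    raw = _filter_members(raw, _protein_coding_symbols(prepared))
    raw["source_db"] = raw["datasource"]
    return {"pathway": raw[["identifier", "name", "source_db", "members"]]}


def _prepare_wikipathways(tables: dict, prepared: dict) -> dict:
    raw = tables["raw"].copy()
    fields = raw["identifier"].str.split("%", expand=True)
    out = pd.DataFrame(
        {
            "identifier": fields[2],
            "name": fields[0],
            "source_db": "WikiPathways",
            "members": raw["members"],
        }
    )
    out = _filter_members(out, _protein_coding_symbols(prepared))
    return {"pathway": out}


def _extract_curie(xrefs: str, prefix: str) -> str:
    for xref in str(xrefs).split(LIST):
        if xref.startswith(prefix + ":"):
            return xref.split(":", 1)[1]
    return ""


def _prepare_go(tables: dict, prepared: dict) -> dict:
    annotations = tables["annotation"].copy()
    annotations["evidence"] = annotations["evidence_code"].map(translate_evidence_code)
    out = dict(tables)
    out["annotation"] = annotations
    return out


def _prepare_clinvar(tables: dict, prepared: dict) -> dict:
    combined = pd.concat(
        [tables["full"], tables["variation"]], ignore_index=True
    )
    variant = dedupe_entities(combined, ["identifier"])
    return {"variant": variant, "drug_assoc": tables["drug_assoc"]}


def _prepare_drugbank(tables: dict, prepared: dict) -> dict:
    out = dict(tables)
    structures = tables["structure"]
    smiles = dict(zip(structures["DRUGBANK_ID"], structures["SMILES"]))
    drugs = tables["drug"].copy()
    drugs["smiles"] = drugs["identifier"].map(lambda i: smiles.get(i, ""))
    out["drug"] = drugs
    del out["structure"]
    proteins = prepared.get("uniprot", {}).get("tables", {}).get("protein")
    if proteins is not None:
        out["target"] = filter_in_identifier_list(
            tables["target"], "uniprot_id", proteins["identifier"].astype(str)
        )
    return out


def _prepare_hpo(tables: dict, prepared: dict) -> dict:
    terms = tables["term"].copy()
    is_a = tables.get("is_a", pd.DataFrame(columns=["source_id", "target_id"]))
    parents = dict(zip(is_a["source_id"], is_a["target_id"]))

    def under_abnormality(term_id: str) -> bool:
        seen = set()
        current = term_id
        while current in parents and current not in seen:
            seen.add(current)
            current = parents[current]
            if current == "HP:0000118":
                return True
        return False

    terms = terms[terms["identifier"].map(under_abnormality)].reset_index(drop=True)
    terms["umls_id"] = terms["xrefs"].map(lambda x: _extract_curie(x, "UMLS"))
    terms["mesh_id"] = terms["xrefs"].map(lambda x: _extract_curie(x, "MSH"))
    return {"term": terms, "is_a": is_a, "annotation": tables["annotation"]}


PREPARERS = {
    "pathway_commons": _prepare_pathway_commons,
    "wikipathways": _prepare_wikipathways,
    "go": _prepare_go,
    "clinvar": _prepare_clinvar,
    "drugbank": _prepare_drugbank,
    "hpo": _prepare_hpo,
}

#: Preparation order: sources whose output other preparers consume first.
PREPARE_ORDER = (
    "entrez", "uniprot", "mondo", "disease_ontology", "omim",
    "pathway_commons", "wikipathways", "go", "iid", "reactome", "clinvar",
    "drugbank", "hpo", "ctd", "ndfrt", "sider", "aeolus", "pharmgkb", "dbsnp",
)


def prepare_corpus(
    corpus_dir: Path | str, registry: dict | None = None
) -> dict[str, dict]:
    """Run every adapter plus its preparation step.

    Returns ``{source: {"tables": {label: DataFrame}, "graph": GraphStore
    or None, "report": run report}}`` in preparation order.
    """
    corpus_dir = Path(corpus_dir)
    registry = bundled_adapter_registry() if registry is None else registry
    missing = [s for s in PREPARE_ORDER if s not in registry]
    if missing:
        raise ConfigurationError(f"adapter configs missing for {missing}")
    prepared: dict[str, dict] = {}
    for source in PREPARE_ORDER:
        spec = registry[source]
        node_tables, edge_tables, report = adapters.run_adapter(spec, corpus_dir)
        graph = None
        for binding in spec.inputs.values():
            if binding.get("format") == "graphml":
                graph = graphml.read_graphml(corpus_dir / binding["path"])
        tables = dict(node_tables)
        preparer = PREPARERS.get(source)
        if preparer is not None:
            tables = preparer(tables, prepared)
        prepared[source] = {"tables": tables, "graph": graph, "report": report}
    return prepared


# -------------------------------------------------------------- integration


def integrate_source(
    store: GraphStore, source: str, tables: dict[str, pd.DataFrame],
    graph: GraphStore | None = None,
) -> dict[str, int]:
    """Load one prepared source into the store as a disconnected subgraph.

    Table rows become nodes labelled ``<source>__<label>``; graphs keep
    their native edges with prefixed type names.  Every entity carries the
    ``source`` marker so final extraction can drop it.
    """
    counts: dict[str, int] = {}
    for label in sorted(tables):
        df = tables[label]
        if "identifier" not in df.columns:
            df = df.copy()
            df.insert(0, "identifier", [f"{label}-{i}" for i in range(len(df))])
        counts[label] = load_node_table(
            df, f"{source}__{label}", store,
            duplicate_policy="merge", extra_properties={"source": source},
        )
    if graph is not None:
        id_map: dict[str, str] = {}
        for node_id in sorted(graph.nodes):
            node = graph.nodes[node_id]
            labels = [f"{source}__{label}" for label in node.labels]
            id_map[node_id] = store.add_node(
                labels, {**node.properties, "source": source}
            )
            counts[node.primary_label] = counts.get(node.primary_label, 0) + 1
        for edge_id in sorted(graph.edges):
            edge = graph.edges[edge_id]
            store.add_edge(
                f"{source}__{edge.type_name}",
                id_map[edge.source_id], id_map[edge.target_id],
                {**edge.properties, "source": source},
            )
    return counts


def integrate_corpus(store: GraphStore, prepared: dict[str, dict]) -> dict:
    report = {}
    for source, bundle in prepared.items():
        report[source] = integrate_source(
            store, source, bundle["tables"], bundle.get("graph")
        )
    return report


def load_xref_tables(corpus_dir: Path | str) -> dict[str, XrefTable]:
    """Generic cross-reference tables standing in for licensed mapping
    systems; one XrefTable per ``xrefs_<a>_<b>.tsv`` file."""
    tables: dict[str, XrefTable] = {}
    for path in sorted(Path(corpus_dir).glob("xrefs_*.tsv")):
        name = path.stem.removeprefix("xrefs_")
        a, b = name.split("_", 1)
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        tables[name] = XrefTable.from_table(df, a, b)
    return tables


# ------------------------------------------------------------ full pipeline


def run_pipeline(corpus_dir: Path | str, registry: dict | None = None) -> dict:
    """Build the merged graph from a corpus directory.

    Returns a dict with the full store (source subgraphs included), the
    extracted merged graph, validation reports, and per-stage reports.
    """
    corpus_dir = Path(corpus_dir)
    prepared = prepare_corpus(corpus_dir, registry)
    store = graphml.read_graphml(corpus_dir / "hetionet.graphml")
    integration_report = integrate_corpus(store, prepared)
    ctx = MergeContext(xref_tables=load_xref_tables(corpus_dir))
    plan = load_merge_plan()
    merge_report = run_merge(store, plan, ROUTINES, ctx)
    extracted = extract_merged_subgraph(store)
    validations = {
        "edge_names": validate_edge_names(extracted),
        "resource_tags": validate_resource_tags(extracted),
        "human_only": check_human_only(extracted),
    }
    return {
        "store": store,
        "extracted": extracted,
        "context": ctx,
        "reports": {
            "prepare": {s: b["report"] for s, b in prepared.items()},
            "integrate": integration_report,
            "merge": merge_report,
        },
        "validations": validations,
    }


def compare_to_ground_truth(extracted: GraphStore, corpus_dir: Path | str) -> dict:
    """Set comparison of the extracted graph against the generator's
    recorded expectation; empty difference lists mean exact agreement."""
    corpus_dir = Path(corpus_dir)
    expected_nodes = pd.read_csv(
        corpus_dir / "ground_truth" / "expected_nodes.tsv", sep="\t", dtype=str
    )
    expected_edges = pd.read_csv(
        corpus_dir / "ground_truth" / "expected_edges.tsv", sep="\t", dtype=str,
        keep_default_na=False,
    )
    want_nodes = {
        (row["identifier"], row["labels"]) for _, row in expected_nodes.iterrows()
    }
    have_nodes = {
        (node.identifier or "", ":".join(sorted(node.labels)))
        for node in extracted.nodes.values()
    }
    want_edges = {
        (row["type_name"], row["source"], row["target"])
        for _, row in expected_edges.iterrows()
    }
    have_edges = {
        (
            edge.type_name,
            extracted.nodes[edge.source_id].identifier or "",
            extracted.nodes[edge.target_id].identifier or "",
        )
        for edge in extracted.edges.values()
    }
    return {
        "nodes_missing": sorted(want_nodes - have_nodes),
        "nodes_unexpected": sorted(have_nodes - want_nodes),
        "edges_missing": sorted(want_edges - have_edges),
        "edges_unexpected": sorted(have_edges - want_edges),
        "node_match": want_nodes == have_nodes,
        "edge_match": want_edges == have_edges,
    }
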