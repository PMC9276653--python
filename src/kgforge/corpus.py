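"""Generate the miniature multi-source corpus with recorded ground truth.

The corpus emulates, at toy scale, the full source landscape of a
pharmacological hetnet build: a seed hetnet (GraphML), OBO ontologies for
diseases, phenotypes and GO terms, a gene-info table with mixed taxa,
GAF-style annotations, GMT gene sets, drug/target/outcome/annotation
tables, two variant releases, SDF structures, stub rs-identifier and
cross-reference tables.  Licensed resources are represented purely by
generic stand-in tables; every file is synthetic.

Ground truth — the expected merged node set, edge set, and filter
survivor counts — is computed constructively while planting the data,
never by running the pipeline, so it can serve as an independent oracle
for the end-to-end build.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .fixtures import FixtureManifest, SMILES_POOL, pool_pair_similar
from .graph import GraphStore
from . import graphml

LIST = "|"


@dataclass
class GroundTruth:
    """Constructively computed expectation for the merged, extracted graph."""

    nodes: dict[str, frozenset[str]] = field(default_factory=dict)  # identifier -> labels
    edges: set[tuple[str, str, str]] = field(default_factory=set)  # (type, src, dst)
    counts: dict[str, int] = field(default_factory=dict)

    def node(self, identifier: str, *labels: str) -> None:
        self.nodes[identifier] = frozenset(labels)

    def edge(self, type_name: str, src: str, dst: str) -> None:
        self.edges.add((type_name, src, dst))


def _write_tsv(path: Path, columns: list[str], rows: list[dict]) -> None:
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(str(row.get(c, "")) for c in columns))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _obo_stanza(term_id: str, name: str, **tags) -> str:
    lines = ["[Term]", f"id: {term_id}", f"name: {name}"]
    for xref in tags.get("xrefs", ()):
        lines.append(f"xref: {xref}")
    for parent in tags.get("is_a", ()):
        lines.append(f"is_a: {parent}")
    for syn in tags.get("synonyms", ()):
        lines.append(f'synonym: "{syn}" EXACT []')
    if tags.get("definition"):
        lines.append(f'def: "{tags["definition"]}" []')
    if tags.get("namespace"):
        lines.append(f"namespace: {tags['namespace']}")
    if tags.get("obsolete"):
        lines.append("is_obsolete: true")
    return "\n".join(lines) + "\n"


def _sdf_record(identifier: str, smiles: str) -> str:
    # synthetic placeholder structure block; downstream fingerprinting
    # consumes the SMILES property
    return (
        f"{identifier}\n  synthetic\n\n  0  0  0  0  0  0  0  0  0  0999 V2000\n"
        "M  END\n"
        f"> <DRUGBANK_ID>\n{identifier}\n\n"
        f"> <SMILES>\n{smiles}\n\n"
        "$$$$\n"
    )


def generate_corpus(manifest: FixtureManifest, out_dir: Path | str) -> GroundTruth:
    """Write the corpus under ``out_dir`` and return (and record) its truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "ground_truth").mkdir(exist_ok=True)
    rng = random.Random(manifest.seed)
    truth = GroundTruth()

    # ---------------------------------------------------------------- extras
    extra_genes = [
        {"gene_id": str(2000 + i), "symbol": f"GENE{i}", "in_seed": i < int(
            manifest.n_extra_genes * manifest.extra_gene_overlap)}
        for i in range(manifest.n_extra_genes)
    ]
    extra_diseases = [
        {
            "mondo": f"MONDO:10{i:02d}", "doid": f"DOID:10{i:02d}",
            "name": f"synthetic disease {i}",
            "in_seed": i < int(manifest.n_extra_diseases * manifest.extra_disease_overlap),
        }
        for i in range(manifest.n_extra_diseases)
    ]
    pool_keys = sorted(SMILES_POOL)
    extra_compounds = [
        {
            "db_id": f"DB1{i:02d}", "name": f"synthetic compound {i}",
            "pool": rng.choice(pool_keys),
            "in_seed": i < int(manifest.n_extra_compounds * manifest.extra_compound_overlap),
        }
        for i in range(manifest.n_extra_compounds)
    ]
    drug_names = ["warfarin", "aspirin", "caffeine"]
    drug_by_name = {"warfarin": "DB001", "aspirin": "DB002", "caffeine": "DB003"}
    extra_pairs = [
        {
            "outcome": f"C1{i:02d}", "outcome_name": f"synthetic outcome {i}",
            "drug_name": rng.choice(drug_names),
            "frequency": round(rng.uniform(0.0, 0.3), 3),
            "count": rng.randint(0, 300),
        }
        for i in range(manifest.n_extra_outcome_pairs)
    ]
    variant_genes = ["1001", "1002", "1003", "1005", "1006"]
    n_missing = int(manifest.n_extra_variants * manifest.extra_variant_missing_rs)
    extra_variants = [
        {
            "vcv": f"VCV1{i:02d}", "rs": f"rs{20000 + i}",
            "gene": rng.choice(variant_genes),
            "missing_rs": i < n_missing,  # absent from the current rs stub list
        }
        for i in range(manifest.n_extra_variants)
    ]

    # ----------------------------------------------------------- seed hetnet
    seed = GraphStore()

    def seed_node(labels, identifier, name, **props):
        return seed.add_node(
            list(labels),
            {
                "identifier": identifier, "name": name,
                "resource": ["Hetionet"], "hetionet_id": identifier, **props,
            },
        )

    def seed_edge(type_name, src, dst):
        seed.add_edge(
            type_name, src, dst,
            {"resource": ["Hetionet"], "hetionet_resource": "true"},
        )

    dis = {
        d: seed_node(["Disease"], d, n)
        for d, n in [
            ("DOID:1", "alzheimer disease"), ("DOID:2", "hypertension"),
            ("DOID:3", "forgotten disease"), ("DOID:4", "epilepsy"),
        ]
    }
    for extra in extra_diseases:
        if extra["in_seed"]:
            dis[extra["doid"]] = seed_node(["Disease"], extra["doid"], extra["name"])
    gene = {
        g: seed_node(["Gene"], g, s)
        for g, s in [
            ("1001", "CYP2C9"), ("1002", "VKORC1"), ("1003", "F5"),
            ("1004", "OLDGENE"), ("1005", "APOE"),
        ]
    }
    for extra in extra_genes:
        if extra["in_seed"]:
            gene[extra["gene_id"]] = seed_node(["Gene"], extra["gene_id"], extra["symbol"])
    comp = {
        c: seed_node(["Compound"], c, n)
        for c, n in [
            ("DB001", "warfarin"), ("DB002", "aspirin"), ("DB003", "caffeine"),
            ("DB004", "forgotten drug"), ("DB005", "ibuprofen"),
        ]
    }
    for extra in extra_compounds:
        if extra["in_seed"]:
            comp[extra["db_id"]] = seed_node(["Compound"], extra["db_id"], extra["name"])
    se = {
        "C0001": seed_node(["SideEffect"], "C0001", "nausea", umls_id="C0001"),
        "C0002": seed_node(["SideEffect"], "C0002", "headache", umls_id="C0002"),
    }
    sym = {
        "D0001": seed_node(["Symptom"], "D0001", "Fever", mesh_id="D0001"),
        "D0002": seed_node(["Symptom"], "D0002", "cough", mesh_id="D0002"),
    }
    pw = {
        "PC1": seed_node(["Pathway"], "PC1", "coagulation cascade"),
        "WP1": seed_node(["Pathway"], "WP1", "caffeine metabolism"),
    }
    go = {
        "GO:0001": seed_node(["BiologicalProcess"], "GO:0001", "blood coagulation"),
        "GO:0002": seed_node(["CellularComponent"], "GO:0002", "endoplasmic reticulum membrane"),
        "GO:0003": seed_node(["MolecularFunction"], "GO:0003", "monooxygenase activity"),
    }
    pc_old = seed_node(["PharmacologicalClass"], "N0001", "anticoagulants")

    seed_edge("TREATS_CtD", comp["DB001"], dis["DOID:2"])
    seed_edge("TREATS_CtD", comp["DB004"], dis["DOID:1"])
    seed_edge("PALLIATES_CpD", comp["DB002"], dis["DOID:4"])
    seed_edge("CAUSES_CcSE", comp["DB002"], se["C0001"])
    seed_edge("BINDS_CbG", comp["DB001"], gene["1001"])
    seed_edge("BINDS_CbG", comp["DB003"], gene["1004"])
    seed_edge("DOWNREGULATES_CdG", comp["DB003"], gene["1005"])
    seed_edge("ASSOCIATES_DaG", dis["DOID:1"], gene["1005"])
    seed_edge("ASSOCIATES_DaG", dis["DOID:3"], gene["1003"])
    seed_edge("PRESENTS_DpS", dis["DOID:2"], sym["D0001"])
    seed_edge("INCLUDES_CiPC", comp["DB001"], pc_old)
    seed_edge("PARTICIPATES_GpPW", gene["1001"], pw["PC1"])
    seed_edge("RESEMBLES_CrC", comp["DB001"], comp["DB002"])
    graphml.write_graphml(seed, out / "hetionet.graphml")
    # seed edges surviving the whole build (endpoints persist; types renamed)
    truth.edge("PALLIATES_CHpD", "DB002", "MONDO:0004")
    truth.edge("DOWNREGULATES_CHdG", "DB003", "1005")
    truth.edge("ASSOCIATES_DaG", "MONDO:0001", "1005")

    # ----------------------------------------------------------------- mondo
    mondo_terms = [
        ("MONDO:0001", "alzheimer disease",
         {"xrefs": ["DOID:1", "UMLS:C0011"], "is_a": []}),
        ("MONDO:0002", "hypertension",
         {"xrefs": ["DOID:2", "OMIM:600001", "UMLS:C0004"], "is_a": []}),
        ("MONDO:0004", "epilepsy",
         {"xrefs": ["DOID:4", "UMLS:C0008"], "is_a": []}),
        ("MONDO:0005", "diabetes mellitus",
         {"xrefs": ["ORPHA:777"], "is_a": ["MONDO:0002"]}),
        ("MONDO:0006", "migraine",
         {"xrefs": ["UMLS:C0003"], "is_a": ["MONDO:0002"]}),
    ]
    for extra in extra_diseases:
        mondo_terms.append(
            (extra["mondo"], extra["name"],
             {"xrefs": [extra["doid"]] if extra["in_seed"] else [], "is_a": []})
        )
    stanzas = [
        _obo_stanza(t, n, xrefs=x["xrefs"], is_a=x["is_a"]) for t, n, x in mondo_terms
    ]
    stanzas.append(
        _obo_stanza("MONDO:0007", "obsolete condition", is_a=["MONDO:0001"], obsolete=True)
    )
    (out / "mondo.obo").write_text(
        "format-version: 1.2\n\n" + "\n".join(stanzas), encoding="utf-8"
    )
    for term_id, name, extra in mondo_terms:
        truth.node(term_id, "Disease", "Phenotype")
        for parent in extra["is_a"]:
            truth.edge("IS_A_DiaD", term_id, parent)

    # -------------------------------------------------------------------- DO
    do_stanzas = [
        _obo_stanza("DOID:1", "Alzheimer's disease", definition="a tauopathy"),
        _obo_stanza("DOID:2", "hypertension", definition="high blood pressure"),
        _obo_stanza("DOID:4", "epilepsy", definition="recurrent seizures",
                    is_a=["DOID:2"]),
        _obo_stanza("DOID:9", "unmapped disease"),
    ]
    (out / "doid.obo").write_text(
        "format-version: 1.2\n\n" + "\n".join(do_stanzas), encoding="utf-8"
    )
    truth.edge("IS_A_DiaD", "MONDO:0004", "MONDO:0002")

    # ---------------------------------------------------------------- entrez
    gene_rows = [
        {"tax_id": "9606", "GeneID": "1001", "Symbol": "CYP2C9",
         "Synonyms": "CPC9|P450IIC9", "description": "cytochrome P450 2C9",
         "type_of_gene": "protein-coding"},
        {"tax_id": "9606", "GeneID": "1002", "Symbol": "VKORC1", "Synonyms": "",
         "description": "vitamin K epoxide reductase", "type_of_gene": "protein-coding"},
        {"tax_id": "9606", "GeneID": "1003", "Symbol": "F5", "Synonyms": "",
         "description": "coagulation factor V", "type_of_gene": "protein-coding"},
        {"tax_id": "9606", "GeneID": "1005", "Symbol": "APOE", "Synonyms": "",
         "description": "apolipoprotein E", "type_of_gene": "protein-coding"},
        {"tax_id": "9606", "GeneID": "1006", "Symbol": "TPMT", "Synonyms": "",
         "description": "thiopurine methyltransferase", "type_of_gene": "protein-coding"},
        {"tax_id": "9606", "GeneID": "1007", "Symbol": "MIR1", "Synonyms": "",
         "description": "microRNA 1", "type_of_gene": "ncRNA"},
        {"tax_id": "63221", "GeneID": "1101", "Symbol": "NEAND1", "Synonyms": "",
         "description": "archaic gene", "type_of_gene": "protein-coding"},
        {"tax_id": "741158", "GeneID": "1102", "Symbol": "DENI1", "Synonyms": "",
         "description": "archaic gene", "type_of_gene": "protein-coding"},
    ]
    for extra in extra_genes:
        gene_rows.append(
            {"tax_id": "9606", "GeneID": extra["gene_id"], "Symbol": extra["symbol"],
             "Synonyms": "", "description": f"synthetic gene {extra['symbol']}",
             "type_of_gene": "protein-coding"}
        )
    _write_tsv(
        out / "gene_info.tsv",
        ["tax_id", "GeneID", "Symbol", "Synonyms", "description", "type_of_gene"],
        gene_rows,
    )
    human_genes = [r for r in gene_rows if r["tax_id"] == "9606"]
    for row in human_genes:
        truth.node(row["GeneID"], "Gene")
    truth.counts["entrez_taxon_survivors"] = len(human_genes)

    # ------------------------------------------------------------------ omim
    _write_tsv(
        out / "omim_entities.tsv",
        ["identifier", "kind", "name", "entrez_id"],
        [
            {"identifier": "OMIM:600001", "kind": "phenotype",
             "name": "hypertension, essential", "entrez_id": ""},
            {"identifier": "OMIM:600002", "kind": "phenotype",
             "name": "rare syndrome X", "entrez_id": ""},
            {"identifier": "OMIM:100001", "kind": "gene", "name": "CYP2C9",
             "entrez_id": "1001"},
            {"identifier": "OMIM:100002", "kind": "gene", "name": "APOE",
             "entrez_id": "1005"},
        ],
    )
    _write_tsv(
        out / "omim_edges.tsv",
        ["phenotype_mim", "gene_mim"],
        [
            {"phenotype_mim": "OMIM:600001", "gene_mim": "OMIM:100001"},
            {"phenotype_mim": "OMIM:600002", "gene_mim": "OMIM:100002"},
        ],
    )
    truth.node("OMIM:600002", "Phenotype")
    truth.edge("ASSOCIATES_DaG", "MONDO:0002", "1001")
    truth.edge("ASSOCIATES_PaG", "OMIM:600002", "1005")

    # -------------------------------------------------------------- pathways
    pc_lines = [
        "PC1\tname: coagulation cascade; datasource: Reactome; organism: 9606"
        "\tCYP2C9\tVKORC1\tF5",
        "PC2\tname: old pathway; datasource: KEGG; organism: 9606\tAPOE",
        "PC3\tname: mouse pathway; datasource: Reactome; organism: 10090\tF5",
        "PC4\tname: mir pathway; datasource: Panther; organism: 9606\tMIR1\tCYP2C9",
    ]
    (out / "pathwaycommons.gmt").write_text("\n".join(pc_lines) + "\n", encoding="utf-8")
    (out / "wikipathways.gmt").write_text(
        "caffeine and theophylline metabolism%WikiPathways_20220410%WP100%"
        "Homo sapiens\thttps://example.org/WP100\tAPOE\tTPMT\tGONE1\n",
        encoding="utf-8",
    )
    truth.node("PC1", "Pathway")
    truth.node("PC4", "Pathway")
    truth.node("WP100", "Pathway")
    for g in ("1001", "1002", "1003"):
        truth.edge("PARTICIPATES_IN_GpiPW", g, "PC1")
    truth.edge("PARTICIPATES_IN_GpiPW", "1001", "PC4")
    truth.edge("PARTICIPATES_IN_GpiPW", "1005", "WP100")
    truth.edge("PARTICIPATES_IN_GpiPW", "1006", "WP100")

    # --------------------------------------------------------------- uniprot
    _write_tsv(
        out / "uniprot_proteins.tsv",
        ["identifier", "name", "gene_symbol", "entrez_id", "taxon_id", "synonyms"],
        [
            {"identifier": "P0001", "name": "Cytochrome P450 2C9",
             "gene_symbol": "CYP2C9", "entrez_id": "1001", "taxon_id": "9606",
             "synonyms": "CYPIIC9"},
            {"identifier": "P0002", "name": "Vitamin K epoxide reductase subunit 1",
             "gene_symbol": "VKORC1", "entrez_id": "1002", "taxon_id": "9606",
             "synonyms": ""},
            {"identifier": "P0003", "name": "Apolipoprotein E",
             "gene_symbol": "APOE", "entrez_id": "1005", "taxon_id": "9606",
             "synonyms": ""},
            {"identifier": "P0004", "name": "Coagulation factor V",
             "gene_symbol": "F5", "entrez_id": "1003", "taxon_id": "9606",
             "synonyms": ""},
        ],
    )
    _write_tsv(
        out / "uniprot_ppi.tsv",
        ["protein_a", "protein_b"],
        [{"protein_a": "P0001", "protein_b": "P0002"}],
    )
    _write_tsv(
        out / "uniprot_disease.tsv",
        ["gene_symbol", "entrez_id", "omim_id", "pubmed_ids"],
        [
            {"gene_symbol": "CYP2C9", "entrez_id": "1001",
             "omim_id": "OMIM:600001", "pubmed_ids": "123"},
            {"gene_symbol": "TPMT", "entrez_id": "1006",
             "omim_id": "OMIM:600001", "pubmed_ids": "456|457"},
            {"gene_symbol": "APOE", "entrez_id": "1005",
             "omim_id": "OMIM:600001", "pubmed_ids": ""},
        ],
    )
    for p in ("P0001", "P0002", "P0004"):
        truth.node(p, "Protein", "Target")
    truth.node("P0003", "Protein")
    truth.node("uniprot:P0001_P0002", "Interaction")
    for p in ("P0001", "P0002"):
        truth.edge("INTERACTS_IiP", "uniprot:P0001_P0002", p)
        truth.edge("INTERACTS_PiI", p, "uniprot:P0001_P0002")
    for g, p in [("1001", "P0001"), ("1002", "P0002"), ("1005", "P0003"), ("1003", "P0004")]:
        truth.edge("PRODUCES_GpP", g, p)
    truth.edge("ASSOCIATES_DaG", "MONDO:0002", "1006")
    truth.counts["uniprot_disease_rows_with_reference"] = 2

    # -------------------------------------------------------------------- GO
    go_stanzas = [
        _obo_stanza("GO:0001", "blood coagulation", namespace="biological_process"),
        _obo_stanza("GO:0004", "xenobiotic metabolic process",
                    namespace="biological_process", is_a=["GO:0001"]),
        _obo_stanza("GO:0002", "endoplasmic reticulum membrane",
                    namespace="cellular_component"),
        _obo_stanza("GO:0005", "cytoplasm", namespace="cellular_component"),
        _obo_stanza("GO:0003", "monooxygenase activity",
                    namespace="molecular_function"),
    ]
    (out / "go.obo").write_text(
        "format-version: 1.2\n\n" + "\n".join(go_stanzas), encoding="utf-8"
    )
    gaf_lines = [
        "!gaf-version: 2.2",
        "UniProtKB\tP0001\tCYP2C9\tenables\tGO:0003\tPMID:1\tEXP",
        "UniProtKB\tP0002\tVKORC1\tlocated_in\tGO:0002\tPMID:2\tIDA",
        "UniProtKB\tP0003\tAPOE\tinvolved_in\tGO:0004\tPMID:3\tIEA",
    ]
    (out / "goa.gaf").write_text("\n".join(gaf_lines) + "\n", encoding="utf-8")
    truth.node("GO:0001", "BiologicalProcess")
    truth.node("GO:0004", "BiologicalProcess")
    truth.node("GO:0002", "CellularComponent")
    truth.node("GO:0005", "CellularComponent")
    truth.node("GO:0003", "MolecularFunction")
    truth.edge("IS_A_BPiaBP", "GO:0004", "GO:0001")
    truth.edge("ENABLES_PeMF", "P0001", "GO:0003")
    truth.edge("ENABLES_GeMF", "1001", "GO:0003")
    truth.edge("LOCATED_IN_PliCC", "P0002", "GO:0002")
    truth.edge("LOCATED_IN_GliCC", "1002", "GO:0002")
    truth.edge("INVOLVED_IN_PiiBP", "P0003", "GO:0004")
    truth.edge("INVOLVED_IN_GiiBP", "1005", "GO:0004")

    # ------------------------------------------------------------------- IID
    _write_tsv(
        out / "iid_ppi.tsv",
        ["protein_a", "protein_b", "evidence_types", "cc_name"],
        [
            {"protein_a": "P0001", "protein_b": "P0003",
             "evidence_types": "exp", "cc_name": "cytoplasm"},
            {"protein_a": "P0002", "protein_b": "P0003",
             "evidence_types": "pred", "cc_name": ""},
            {"protein_a": "P0001", "protein_b": "P0002",
             "evidence_types": "exp|pred", "cc_name": ""},
        ],
    )
    for pair in (("P0001", "P0003"), ("P0001", "P0002")):
        ident = f"iid:{pair[0]}_{pair[1]}"
        truth.node(ident, "Interaction")
        for p in pair:
            truth.edge("INTERACTS_IiP", ident, p)
            truth.edge("INTERACTS_PiI", p, ident)
    truth.edge("MIGHT_SUBCELLULAR_LOCATES_ImslCC", "iid:P0001_P0003", "GO:0005")
    truth.counts["iid_experimental_rows"] = 2

    # -------------------------------------------------------------- reactome
    react = GraphStore()
    rx: dict[str, str] = {}
    rx["R-HSA-1"] = react.add_node(
        ["Pathway"], {"identifier": "R-HSA-1", "name": "coagulation cascade"}
    )
    rx["R-HSA-2"] = react.add_node(
        ["Pathway"], {"identifier": "R-HSA-2", "name": "platelet activation"}
    )
    rx["R-RLE-1"] = react.add_node(
        ["Reaction"],
        {"identifier": "R-RLE-1", "name": "factor activation", "species": "Homo sapiens",
         "pubmed_ids": ["111"], "input_chemical": "caffeine",
         "output_chemical": "aspirin"},
    )
    rx["R-RLE-2"] = react.add_node(
        ["BlackBoxEvent"],
        {"identifier": "R-RLE-2", "name": "unreviewed event", "species": "Homo sapiens"},
    )
    rx["R-RLE-3"] = react.add_node(
        ["Polymerisation"],
        {"identifier": "R-RLE-3", "name": "mouse event", "species": "Mus musculus",
         "pubmed_ids": ["333"]},
    )
    rx["R-RLE-4"] = react.add_node(
        ["Reaction"],
        {"identifier": "R-RLE-4", "name": "fibrin formation", "species": "Homo sapiens",
         "pubmed_ids": ["222"], "protein_input": "P0004"},
    )
    react.add_node(
        ["Treatment"],
        {"identifier": "T-REACT-1", "chemical_name": "warfarin",
         "doid": "DOID:2", "go_id": "GO:0002"},
    )
    dref = react.add_node(["DiseaseRef"], {"identifier": "DREF-1", "doid": "DOID:2"})
    gref = react.add_node(["GoRef"], {"identifier": "GREF-1", "go_id": "GO:0002"})
    react.add_edge("precedingEvent", rx["R-HSA-2"], rx["R-HSA-1"])
    react.add_edge("hasEvent", rx["R-HSA-1"], rx["R-RLE-1"])
    react.add_edge("hasEvent", rx["R-HSA-1"], rx["R-RLE-2"])
    react.add_edge("precedingEvent", rx["R-RLE-1"], rx["R-RLE-4"])
    react.add_edge("compartment", rx["R-RLE-1"], gref)
    react.add_edge("disease", rx["R-RLE-4"], dref)
    react.add_edge("disease", rx["R-HSA-1"], dref)
    graphml.write_graphml(react, out / "reactome.graphml")
    truth.node("R-HSA-2", "Pathway")
    truth.node("R-RLE-1", "Reaction", "ReactionLikeEvent")
    truth.node("R-RLE-4", "Reaction", "ReactionLikeEvent")
    truth.edge("PRECEDING_REACTION_PWprPW", "R-HSA-2", "PC1")
    truth.edge("PARTICIPATES_IN_PWpiRLE", "PC1", "R-RLE-1")
    truth.edge("PRECEDING_REACTION_RLEprRLE", "R-RLE-1", "R-RLE-4")
    truth.edge("IN_COMPARTMENT_RLEicCC", "R-RLE-1", "GO:0002")
    truth.edge("LEADS_TO_DISEASE_RLEltdD", "R-RLE-4", "MONDO:0002")
    truth.edge("LEADS_TO_PWltD", "PC1", "MONDO:0002")
    # chemical-phase reactome additions
    truth.node("T-REACT-1", "Treatment")
    truth.edge("TREATS_CHtT", "DB001", "T-REACT-1")
    truth.edge("TREATS_TtD", "T-REACT-1", "MONDO:0002")
    truth.edge("IS_LOCALIZED_IN_TiliCC", "T-REACT-1", "GO:0002")
    truth.edge("HAS_INPUT_RLEhiCH", "R-RLE-1", "DB003")
    truth.edge("HAS_OUTPUT_RLEhoCH", "R-RLE-1", "DB002")
    truth.edge("IS_INPUT_OF_PiioRLE", "P0004", "R-RLE-4")

    # --------------------------------------------------------------- clinvar
    variation_rows = [
        {"identifier": "VCV001", "kind": "GeneVariant",
         "name": "NM_000771.3(CYP2C9):c.430C>T (p.Arg144Cys)",
         "rs_id": "rs1799853", "gene_id": "1001"},
        {"identifier": "VCV002", "kind": "GeneVariant",
         "name": "NM_000771.3(CYP2C9):c.1075A>C (p.Ile359Leu)",
         "rs_id": "rs1057910", "gene_id": "1001"},
        {"identifier": "VCV003", "kind": "GeneVariant",
         "name": "NM_024006.4(VKORC1):c.-1639G>A",
         "rs_id": "rs9923231", "gene_id": "1002"},
        {"identifier": "VCV004", "kind": "Haplotype", "name": "CYP2C9*2 haplotype",
         "member_variant": "VCV001"},
        {"identifier": "VCV005", "kind": "Genotype", "name": "compound genotype",
         "haplotype": "VCV004", "variant": "VCV002"},
        {"identifier": "VCV007", "kind": "GeneVariant",
         "name": "VKORC1 promoter secondary record", "rs_id": "rs9923231"},
    ]
    full_rows = [
        {"identifier": "VCV001", "kind": "GeneVariant",
         "name": "NM_000771.3(CYP2C9):c.430C>T (p.Arg144Cys)",
         "rs_id": "rs1799853", "gene_id": "1001", "trait": "warfarin response"},
        {"identifier": "VCV002", "kind": "GeneVariant",
         "name": "NM_000771.3(CYP2C9):c.1075A>C (p.Ile359Leu)",
         "rs_id": "rs1057910", "gene_id": "1001", "trait": "warfarin response"},
        {"identifier": "VCV006", "kind": "GeneVariant", "name": "APOE e4 allele",
         "rs_id": "rs1801131", "gene_id": "1005"},
        {"identifier": "VCV010", "kind": "GeneVariant", "name": "withdrawn variant",
         "rs_id": "rs9999999", "gene_id": "1003"},
    ]
    for extra in extra_variants:
        full_rows.append(
            {"identifier": extra["vcv"], "kind": "GeneVariant",
             "name": f"synthetic variant {extra['vcv']}", "rs_id": extra["rs"],
             "gene_id": extra["gene"]}
        )
    columns = ["identifier", "kind", "name", "rs_id", "gene_id",
               "member_variant", "haplotype", "variant", "trait"]
    _write_tsv(out / "clinvar_variation.tsv", columns, variation_rows)
    _write_tsv(out / "clinvar_full.tsv", columns, full_rows)
    _write_tsv(
        out / "clinvar_drug_assoc.tsv",
        ["variant_id", "drug_name", "association_type"],
        [
            {"variant_id": "VCV002", "drug_name": "warfarin",
             "association_type": "efficacy_dosage"},
            {"variant_id": "VCV003", "drug_name": "warfarin",
             "association_type": "dosage"},
            {"variant_id": "VCV001", "drug_name": "warfarin",
             "association_type": ""},
        ],
    )
    for vcv, gene_id in [
        ("VCV001", "1001"), ("VCV002", "1001"), ("VCV003", "1002"), ("VCV006", "1005"),
    ]:
        truth.node(vcv, "GeneVariant", "Variant")
        truth.edge("HAS_GhV", gene_id, vcv)
    truth.node("VCV007", "GeneVariant", "Variant")
    truth.node("VCV004", "Haplotype", "Variant")
    truth.node("VCV005", "Genotype", "Variant")
    truth.edge("HAS_HhGV", "VCV004", "VCV001")
    truth.edge("HAS_GThH", "VCV005", "VCV004")
    truth.edge("HAS_GThGV", "VCV005", "VCV002")
    for extra in extra_variants:
        if not extra["missing_rs"]:  # survives the rs-identifier pruning
            truth.node(extra["vcv"], "GeneVariant", "Variant")
            truth.edge("HAS_GhV", extra["gene"], extra["vcv"])
    truth.edge("ASSOCIATES_TO_EFFICACY_DOSAGE_VatedCH", "VCV002", "DB001")
    truth.edge("ASSOCIATES_TO_DOSAGE_VatdCH", "VCV003", "DB001")
    truth.edge("ASSOCIATES_VaCH", "VCV001", "DB001")

    # -------------------------------------------------------------- drugbank
    drug_rows = [
        {"identifier": "DB001", "name": "warfarin", "cas": "81-81-2",
         "inchikey": "WARF-KEY", "pool": "warfarin", "atc_codes": "B01AA03"},
        {"identifier": "DB002", "name": "aspirin", "cas": "50-78-2",
         "inchikey": "ASPI-KEY", "pool": "aspirin", "atc_codes": ""},
        {"identifier": "DB003", "name": "caffeine", "cas": "58-08-2",
         "inchikey": "CAFF-KEY", "pool": "caffeine", "atc_codes": ""},
        {"identifier": "DB005", "name": "ibuprofen", "cas": "15687-27-1",
         "inchikey": "IBUP-KEY", "pool": "ibuprofen", "atc_codes": ""},
        {"identifier": "DB006", "name": "acenocoumarol", "cas": "152-72-7",
         "inchikey": "ACENO-KEY", "pool": "acenocoumarol", "atc_codes": ""},
        {"identifier": "DB007", "name": "synthetic ethanol formulation",
         "cas": "64-17-5", "inchikey": "ETOH-KEY", "pool": "ethanol",
         "atc_codes": ""},
    ]
    for extra in extra_compounds:
        drug_rows.append(
            {"identifier": extra["db_id"], "name": extra["name"], "cas": "",
             "inchikey": f"KEY-{extra['db_id']}", "pool": extra["pool"],
             "atc_codes": ""}
        )
    _write_tsv(
        out / "drugbank_drugs.tsv",
        ["identifier", "name", "cas", "inchikey", "atc_codes"],
        drug_rows,
    )
    (out / "drugbank_structures.sdf").write_text(
        "".join(
            _sdf_record(r["identifier"], SMILES_POOL[r["pool"]]) for r in drug_rows
        ),
        encoding="utf-8",
    )
    _write_tsv(
        out / "drugbank_salts.tsv",
        ["identifier", "name", "parent"],
        [{"identifier": "SALT1", "name": "warfarin sodium", "parent": "DB001"}],
    )
    _write_tsv(
        out / "drugbank_products.tsv",
        ["identifier", "name", "drug"],
        [{"identifier": "PROD1", "name": "Coumadin 5 mg tablet", "drug": "DB001"}],
    )
    _write_tsv(
        out / "drugbank_interactions.tsv",
        ["drug_a", "drug_b"],
        [{"drug_a": "DB001", "drug_b": "DB002"}],
    )
    _write_tsv(
        out / "drugbank_adr.tsv",
        ["rs_id", "drug_id"],
        [
            {"rs_id": "rs1799853", "drug_id": "DB001"},
            {"rs_id": "rs9999999", "drug_id": "DB002"},
            {"rs_id": "rs5555", "drug_id": "DB001"},
        ],
    )
    _write_tsv(
        out / "drugbank_targets.tsv",
        ["drug_id", "uniprot_id", "action", "category", "pubmed_ids"],
        [
            {"drug_id": "DB001", "uniprot_id": "P0001", "action": "binds",
             "category": "target", "pubmed_ids": "9"},
            {"drug_id": "DB001", "uniprot_id": "P0002", "action": "binds",
             "category": "target", "pubmed_ids": "10"},
            {"drug_id": "DB003", "uniprot_id": "P0003", "action": "inhibits",
             "category": "target", "pubmed_ids": ""},
            {"drug_id": "DB002", "uniprot_id": "P0004", "action": "binds",
             "category": "target", "pubmed_ids": "11"},
            {"drug_id": "DB002", "uniprot_id": "P9999", "action": "binds",
             "category": "target", "pubmed_ids": "12"},
        ],
    )
    _write_tsv(
        out / "drugbank_atc.tsv",
        ["code", "name", "parent_code", "parent_name"],
        [
            {"code": "B01AA", "name": "Vitamin K antagonists",
             "parent_code": "B01", "parent_name": "Antithrombotic agents"},
        ],
    )
    for row in drug_rows:
        truth.node(row["identifier"], "Compound", "Chemical")
    truth.node("SALT1", "Salt", "Compound", "Chemical")
    truth.node("PROD1", "Product")
    truth.node("rs5555", "GeneVariant", "Variant")
    truth.edge("HAS_ChPR", "DB001", "PROD1")
    truth.edge("PART_OF_CpoSA", "DB001", "SALT1")
    truth.edge("INTERACTS_CiC", "DB001", "DB002")
    truth.edge("COMBINATION_CAUSES_ADR_VccaCH", "VCV001", "DB001")
    truth.edge("COMBINATION_CAUSES_ADR_VccaCH", "rs5555", "DB001")
    resemb = 0
    for i in range(len(drug_rows)):
        for j in range(i + 1, len(drug_rows)):
            if pool_pair_similar(drug_rows[i]["pool"], drug_rows[j]["pool"]):
                a = min(drug_rows[i]["identifier"], drug_rows[j]["identifier"])
                b = max(drug_rows[i]["identifier"], drug_rows[j]["identifier"])
                truth.edge("RESEMBLES_CrC", a, b)
                resemb += 1
    truth.counts["resemblance_edges"] = resemb
    truth.edge("BELONGS_TO_CHbtPC", "DB001", "atc:B01AA")
    truth.edge("BELONGS_TO_PCbtPC", "atc:B01AA", "atc:B01")
    truth.node("atc:B01AA", "PharmacologicalClass")
    truth.node("atc:B01", "PharmacologicalClass")
    truth.edge("BINDS_CHbP", "DB001", "P0001")
    truth.edge("BINDS_CHbP", "DB001", "P0002")
    truth.edge("BINDS_CHbP", "DB002", "P0004")

    # ------------------------------------------------------------------- HPO
    hp_stanzas = [
        _obo_stanza("HP:0000118", "Phenotypic abnormality"),
        _obo_stanza("HP:0000005", "Mode of inheritance"),
        _obo_stanza("HP:0001", "Fever", is_a=["HP:0000118"],
                    xrefs=["UMLS:C0005", "MSH:D0001"]),
        _obo_stanza("HP:0002", "Seizure", is_a=["HP:0000118"],
                    xrefs=["UMLS:C0008"]),
        _obo_stanza("HP:0003", "Autosomal dominant inheritance",
                    is_a=["HP:0000005"]),
    ]
    (out / "hp.obo").write_text(
        "format-version: 1.2\n\n" + "\n".join(hp_stanzas), encoding="utf-8"
    )
    hpoa_lines = [
        "!#- synthetic annotation release",
        "disease_id\tdisease_name\thp_id",
        "OMIM:600001\thypertension, essential\tHP:0001",
        "OMIM:600001\thypertension, essential\tHP:0002",
        "ORPHA:777\tdiabetes mellitus\tHP:0002",
        "OMIM:999999\tunknown disease\tHP:0001",
    ]
    (out / "phenotype.hpoa").write_text("\n".join(hpoa_lines) + "\n", encoding="utf-8")
    truth.node("D0001", "Symptom", "Phenotype")
    truth.node("D0002", "Symptom", "Phenotype")
    truth.node("HP:0002", "Symptom", "Phenotype")
    truth.edge("PRESENTS_DpS", "MONDO:0002", "D0001")
    truth.edge("PRESENTS_DpS", "MONDO:0002", "HP:0002")
    truth.edge("PRESENTS_DpS", "MONDO:0005", "HP:0002")

    # ------------------------------------------------------------------- CTD
    _write_tsv(
        out / "ctd_chemicals.tsv",
        ["identifier", "name", "cas", "inchikey"],
        [
            {"identifier": "MESH:C001", "name": "warfarin sodium salt form",
             "cas": "81-81-2", "inchikey": ""},
            {"identifier": "MESH:C101", "name": "acenocoumarol variant",
             "cas": "", "inchikey": "ACENO-KEY"},
            {"identifier": "MESH:C003", "name": "caffeine", "cas": "", "inchikey": ""},
            {"identifier": "MESH:C100", "name": "novel toxicant", "cas": "",
             "inchikey": ""},
        ],
    )
    _write_tsv(
        out / "ctd_chem_gene.tsv",
        ["chemical_id", "gene_id", "relation", "taxon_id", "pubmed_ids", "target_type"],
        [
            {"chemical_id": "MESH:C001", "gene_id": "1001", "relation": "binds",
             "taxon_id": "9606", "pubmed_ids": "21", "target_type": "gene"},
            {"chemical_id": "MESH:C003", "gene_id": "1006", "relation": "upregulates",
             "taxon_id": "9606", "pubmed_ids": "22", "target_type": "gene"},
            {"chemical_id": "MESH:C100", "gene_id": "1001", "relation": "associates",
             "taxon_id": "9606", "pubmed_ids": "23", "target_type": "gene"},
            {"chemical_id": "MESH:C001", "gene_id": "1005", "relation": "binds",
             "taxon_id": "10090", "pubmed_ids": "24", "target_type": "gene"},
            {"chemical_id": "MESH:C003", "gene_id": "1005", "relation": "binds",
             "taxon_id": "9606", "pubmed_ids": "", "target_type": "gene"},
            {"chemical_id": "MESH:C001", "gene_id": "1002", "relation": "binds",
             "taxon_id": "9606", "pubmed_ids": "25", "target_type": "protein"},
        ],
    )
    _write_tsv(
        out / "ctd_chem_disease.tsv",
        ["chemical_id", "disease_id", "DirectEvidence", "pubmed_ids"],
        [
            {"chemical_id": "MESH:C001", "disease_id": "DOID:2",
             "DirectEvidence": "therapeutic", "pubmed_ids": "31"},
            {"chemical_id": "MESH:C003", "disease_id": "DOID:4",
             "DirectEvidence": "marker/mechanism", "pubmed_ids": "32"},
            {"chemical_id": "MESH:C001", "disease_id": "DOID:1",
             "DirectEvidence": "", "pubmed_ids": "33"},
        ],
    )
    _write_tsv(
        out / "ctd_gene_disease.tsv",
        ["gene_id", "disease_id", "DirectEvidence", "pubmed_ids"],
        [
            {"gene_id": "1003", "disease_id": "DOID:2",
             "DirectEvidence": "marker/mechanism", "pubmed_ids": "34"},
            {"gene_id": "1005", "disease_id": "DOID:1",
             "DirectEvidence": "", "pubmed_ids": "35"},
        ],
    )
    _write_tsv(
        out / "ctd_chem_go.tsv",
        ["chemical_id", "go_id", "relation"],
        [{"chemical_id": "MESH:C001", "go_id": "GO:0001", "relation": "increases"}],
    )
    _write_tsv(
        out / "ctd_pathways.tsv",
        ["pathway_id", "gene_id"],
        [{"pathway_id": "R-HSA-1", "gene_id": "1003"}],
    )
    truth.node("MESH:C100", "Chemical")
    truth.edge("BINDS_CHbG", "DB001", "1001")  # seed edge, matched and updated
    truth.edge("UPREGULATES_CHuG", "DB003", "1006")
    truth.edge("ASSOCIATES_CHaG", "MESH:C100", "1001")
    truth.edge("BINDS_CHbP", "DB001", "P0002")  # via protein-flagged row
    truth.edge("TREATS_CHtD", "DB001", "MONDO:0002")
    truth.edge("INDUCES_CHiD", "DB003", "MONDO:0004")
    truth.edge("ASSOCIATES_DaG", "MONDO:0002", "1003")
    truth.edge("INCREASES_CHiBP", "DB001", "GO:0001")
    truth.edge("PARTICIPATES_IN_GpiPW", "1003", "PC1")
    truth.counts["ctd_direct_evidence_survivors"] = 3

    # ----------------------------------------------------------------- NDFRT
    _write_tsv(
        out / "ndfrt_classes.tsv",
        ["identifier", "name", "kind", "parent"],
        [
            {"identifier": "N0002", "name": "Anticoagulants [MoA]",
             "kind": "mechanism_of_action", "parent": ""},
            {"identifier": "N0003", "name": "Decreased Coagulation [PE]",
             "kind": "physiologic_effect", "parent": "N0002"},
        ],
    )
    _write_tsv(
        out / "ndfrt_edges.tsv",
        ["subject_kind", "subject_ref", "relation", "object_kind", "object_ref"],
        [
            {"subject_kind": "chemical", "subject_ref": "warfarin",
             "relation": "CONTRAINDICATES", "object_kind": "disease",
             "object_ref": "epilepsy"},
            {"subject_kind": "class", "subject_ref": "N0002", "relation": "TREATS",
             "object_kind": "disease", "object_ref": "C0004"},
            {"subject_kind": "class", "subject_ref": "N0002", "relation": "INCLUDES",
             "object_kind": "chemical", "object_ref": "warfarin"},
            {"subject_kind": "chemical", "subject_ref": "aspirin",
             "relation": "PREVENTS", "object_kind": "disease",
             "object_ref": "C0004"},
        ],
    )
    truth.node("N0002", "PharmacologicalClass")
    truth.node("N0003", "PharmacologicalClass")
    truth.edge("INCLUDES_PCiPC", "N0002", "N0003")
    truth.edge("CONTRAINDICATES_CHcD", "DB001", "MONDO:0004")
    truth.edge("TREATS_PCtD", "N0002", "MONDO:0002")
    truth.edge("INCLUDES_PCiCH", "N0002", "DB001")
    truth.edge("PREVENTS_CHpD", "DB002", "MONDO:0002")

    # ----------------------------------------------------------------- SIDER
    _write_tsv(
        out / "sider_side_effects.tsv",
        ["identifier", "name"],
        [
            {"identifier": "C0001", "name": "nausea"},
            {"identifier": "C0006", "name": "bleeding"},
            {"identifier": "C0010", "name": "fever"},
            {"identifier": "C0012", "name": "hypertension"},
            {"identifier": "C0014", "name": "rare syndrome X"},
        ],
    )
    _write_tsv(
        out / "sider_causes.tsv",
        ["drug_name", "se_id"],
        [
            {"drug_name": "aspirin", "se_id": "C0001"},
            {"drug_name": "warfarin", "se_id": "C0006"},
            {"drug_name": "unknown elixir", "se_id": "C0006"},
        ],
    )
    for ident, _name in [
        ("C0001", "nausea"), ("C0006", "bleeding"),
        ("C0010", "fever"), ("C0012", "hypertension"),
        ("C0014", "rare syndrome X"),
    ]:
        truth.node(ident, "SideEffect", "Phenotype")
    truth.edge("CAUSES_CHcSE", "DB002", "C0001")
    truth.edge("CAUSES_CHcSE", "DB001", "C0006")

    # ---------------------------------------------------------------- AEOLUS
    outcome_rows = [
        {"identifier": "C0001", "name": "nausea", "meddra_id": "M0001", "kind": "se"},
        {"identifier": "C0007", "name": "dizziness", "meddra_id": "M0007", "kind": "se"},
        {"identifier": "C0013", "name": "strange reaction", "meddra_id": "", "kind": "se"},
        {"identifier": "C0009", "name": "high blood pressure", "meddra_id": "M0004",
         "kind": "disease"},
    ]
    pair_rows = [
        {"drug_name": "warfarin", "outcome_id": "C0001", "frequency": "0.5",
         "report_count": "150"},
        {"drug_name": "warfarin", "outcome_id": "C0007", "frequency": "0.05",
         "report_count": "500"},
        {"drug_name": "caffeine", "outcome_id": "C0007", "frequency": "0.2",
         "report_count": "50"},
        {"drug_name": "caffeine", "outcome_id": "C0001", "frequency": "0.1",
         "report_count": "100"},
        {"drug_name": "warfarin", "outcome_id": "C0009", "frequency": "0.3",
         "report_count": "120"},
    ]
    for extra in extra_pairs:
        outcome_rows.append(
            {"identifier": extra["outcome"], "name": extra["outcome_name"],
             "meddra_id": "", "kind": "se"}
        )
        pair_rows.append(
            {"drug_name": extra["drug_name"], "outcome_id": extra["outcome"],
             "frequency": str(extra["frequency"]),
             "report_count": str(extra["count"])}
        )
    _write_tsv(
        out / "aeolus_outcomes.tsv",
        ["identifier", "name", "meddra_id", "kind"], outcome_rows,
    )
    _write_tsv(
        out / "aeolus_pairs.tsv",
        ["drug_name", "outcome_id", "frequency", "report_count"], pair_rows,
    )
    truth.node("C0007", "SideEffect", "Phenotype")
    truth.node("C0013", "SideEffect", "Phenotype")
    truth.edge("MIGHT_CAUSES_CHmcSE", "DB001", "C0001")
    truth.edge("MIGHT_CAUSES_CHmcSE", "DB003", "C0001")
    truth.edge("MIGHT_INDUCES_CHmiD", "DB001", "MONDO:0002")
    kept_pairs = 3  # the planted passing pairs above
    for extra in extra_pairs:
        truth.node(extra["outcome"], "SideEffect", "Phenotype")
        if extra["frequency"] >= 0.1 and extra["count"] >= 100:
            truth.edge(
                "MIGHT_CAUSES_CHmcSE", drug_by_name[extra["drug_name"]],
                extra["outcome"],
            )
            kept_pairs += 1
    truth.counts["aeolus_pairs_kept"] = kept_pairs
    truth.counts["aeolus_pairs_total"] = len(pair_rows)

    # -------------------------------------------------------------- pharmgkb
    pgkb = GraphStore()
    pg: dict[str, str] = {}
    pg["PA1"] = pgkb.add_node(
        ["Chemical"], {"identifier": "PA1", "name": "warfarin", "drugbank_id": "DB001"}
    )
    pg["PA_G1"] = pgkb.add_node(
        ["Gene"], {"identifier": "PA_G1", "name": "CYP2C9", "entrez_id": "1001"}
    )
    pg["PA_P1"] = pgkb.add_node(
        ["Phenotype"], {"identifier": "PA_P1", "name": "hypertension", "umls_id": "C0004"}
    )
    pg["PA_P2"] = pgkb.add_node(
        ["Phenotype"], {"identifier": "PA_P2", "name": "weird response"}
    )
    pg["PA_V1"] = pgkb.add_node(
        ["Variant"], {"identifier": "PA_V1", "name": "CYP2C9*2", "rs_id": "rs1799853"}
    )
    pg["PA_V2"] = pgkb.add_node(
        ["Variant"], {"identifier": "PA_V2", "name": "orphan variant", "rs_id": "rs7777"}
    )
    pg["PA_V3"] = pgkb.add_node(
        ["Variant"], {"identifier": "PA_V3", "name": "CYP2C9*3", "rs_id": "rs1057910"}
    )
    pg["CA1"] = pgkb.add_node(
        ["ClinicalAnnotation"],
        {"identifier": "CA1", "evidence_level": "1", "significance": ""},
    )
    pg["CA2"] = pgkb.add_node(
        ["ClinicalAnnotation"],
        {"identifier": "CA2", "evidence_level": "4", "significance": ""},
    )
    pg["VA1"] = pgkb.add_node(
        ["VariantAnnotation"],
        {"identifier": "VA1", "evidence_level": "", "significance": "yes"},
    )
    pg["VA2"] = pgkb.add_node(
        ["VariantAnnotation"],
        {"identifier": "VA2", "evidence_level": "", "significance": "no"},
    )
    pgkb.add_edge("associates", pg["CA1"], pg["PA_G1"])
    pgkb.add_edge("associates", pg["CA1"], pg["PA_V1"])
    pgkb.add_edge("associates", pg["CA1"], pg["PA1"])
    pgkb.add_edge("associates", pg["CA1"], pg["PA_P1"])
    pgkb.add_edge("associates", pg["CA2"], pg["PA_G1"])
    pgkb.add_edge("associates", pg["VA1"], pg["PA_V3"])
    pgkb.add_edge("associates", pg["VA1"], pg["PA1"])
    pgkb.add_edge("associates", pg["VA2"], pg["PA_V1"])
    pgkb.add_edge("evidence", pg["CA1"], pg["VA1"])
    pgkb.add_edge("has_variant", pg["PA_G1"], pg["PA_V1"])
    graphml.write_graphml(pgkb, out / "pharmgkb.graphml")
    truth.node("PA_P2", "Phenotype")
    truth.node("CA1", "ClinicalAnnotation")
    truth.node("VA1", "VariantAnnotation")
    truth.edge("ASSOCIATES_CAaG", "CA1", "1001")
    truth.edge("ASSOCIATES_CAaV", "CA1", "VCV001")
    truth.edge("ASSOCIATES_CAaCH", "CA1", "DB001")
    truth.edge("ASSOCIATES_CAaPT", "CA1", "MONDO:0002")
    truth.edge("ASSOCIATES_VAaV", "VA1", "VCV002")
    truth.edge("ASSOCIATES_VAaCH", "VA1", "DB001")
    truth.edge("HAS_EVIDENCE_CAheVA", "CA1", "VA1")
    truth.counts["pharmgkb_annotations_kept"] = 2

    # ----------------------------------------------------- dbSNP stub, xrefs
    rs_rows = [
        {"rs_id": "rs1799853", "gene_id": "1001"},
        {"rs_id": "rs1057910", "gene_id": "1001"},
        {"rs_id": "rs9923231", "gene_id": "1002"},
        {"rs_id": "rs1801131", "gene_id": "1005"},
        {"rs_id": "rs5555", "gene_id": "1003"},
    ]
    for extra in extra_variants:
        if not extra["missing_rs"]:
            rs_rows.append({"rs_id": extra["rs"], "gene_id": extra["gene"]})
    _write_tsv(out / "dbsnp_rs.tsv", ["rs_id", "gene_id"], rs_rows)
    truth.edge("HAS_GhV", "1003", "rs5555")
    truth.counts["variants_pruned"] = 2 + sum(
        1 for e in extra_variants if e["missing_rs"]
    )  # VCV010, the PharmGKB orphan, and stub-missing extras

    _write_tsv(
        out / "xrefs_meddra_umls.tsv",
        ["meddra", "umls"],
        [
            {"meddra": "M0001", "umls": "C0001"},
            {"meddra": "M0007", "umls": "C0007"},
            {"meddra": "M0004", "umls": "C0004"},
        ],
    )

    # ------------------------------------------------------ EQUAL and allele
    truth.edge("EQUAL_DeSE", "MONDO:0002", "C0012")
    truth.edge("EQUAL_DeS", "MONDO:0004", "HP:0002")
    truth.edge("EQUAL_SeSE", "D0001", "C0010")
    truth.edge("EQUAL_PTeSE", "OMIM:600002", "C0014")
    truth.edge("IS_ALLEL_OF_ViaoV", "VCV003", "VCV007")

    # ------------------------------------------------------------ truth dump
    node_rows = [
        {"identifier": ident, "labels": ":".join(sorted(labels))}
        for ident, labels in sorted(truth.nodes.items())
    ]
    _write_tsv(out / "ground_truth" / "expected_nodes.tsv",
               ["identifier", "labels"], node_rows)
    edge_rows = [
        {"type_name": t, "source": s, "target": d}
        for t, s, d in sorted(truth.edges)
    ]
    _write_tsv(out / "ground_truth" / "expected_edges.tsv",
               ["type_name", "source", "target"], edge_rows)
    truth.counts["expected_nodes"] = len(truth.nodes)
    truth.counts["expected_edges"] = len(truth.edges)
    (out / "ground_truth" / "expected_counts.json").write_text(
        json.dumps(truth.counts, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return truth
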