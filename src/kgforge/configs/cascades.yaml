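# Mapping cascades: ordered resolution strategies per entity class.
# Strategy kinds: identifier (exact value vs a node property), xref
# (bridge through a cross-reference table), name (normalized name and
# synonym comparison), structure (fingerprint similarity).
disease_by_doid:
  target: Disease
  strategies:
    - {kind: identifier, key: doid, node_property: xrefs}
disease_by_omim:
  target: Disease
  strategies:
    - {kind: identifier, key: omim_id, node_property: xrefs}
disease_full:
  target: Disease
  strategies:
    - {kind: identifier, key: omim_id, node_property: xrefs}
    - {kind: identifier, key: orpha_id, node_property: xrefs}
    - {kind: identifier, key: doid, node_property: xrefs}
    - {kind: identifier, key: umls_id, node_property: umls_id}
    - {kind: name, key: name}
disease_by_umls:
  target: Disease
  strategies:
    - {kind: xref, key: meddra_id, xref_table: meddra_umls, node_property: umls_id}
    - {kind: identifier, key: umls_id, node_property: umls_id}
    - {kind: name, key: name}
symptom:
  target: Symptom
  strategies:
    - {kind: identifier, key: mesh_id, node_property: mesh_id}
    - {kind: identifier, key: umls_id, node_property: umls_id}
    - {kind: name, key: name}
gene_by_entrez:
  target: Gene
  strategies:
    - {kind: identifier, key: entrez_id, node_property: identifier}
gene_full:
  target: Gene
  strategies:
    - {kind: identifier, key: entrez_id, node_property: identifier}
    - {kind: identifier, key: gene_symbol, node_property: name}
    - {kind: name, key: name}
protein_by_uniprot:
  target: Protein
  strategies:
    - {kind: identifier, key: uniprot_id, node_property: identifier}
pathway_reactome:
  target: Pathway
  strategies:
    - {kind: identifier, key: reactome_id, node_property: reactome_id}
    - {kind: name, key: name}
chemical_ctd:
  target: Compound
  strategies:
    - {kind: identifier, key: cas, node_property: cas}
    - {kind: identifier, key: umls_id, node_property: umls_id}
    - {kind: identifier, key: rxnorm_id, node_property: rxnorm_id}
    - {kind: identifier, key: unii, node_property: unii}
    - {kind: identifier, key: inchikey, node_property: inchikey}
    - {kind: identifier, key: mesh_id, node_property: mesh_id}
    - {kind: name, key: name}
chemical_by_name:
  target: Chemical
  strategies:
    - {kind: identifier, key: inchikey, node_property: inchikey}
    - {kind: name, key: name}
chemical_pgkb:
  target: Chemical
  strategies:
    - {kind: identifier, key: drugbank_id, node_property: identifier}
    - {kind: identifier, key: rxnorm_id, node_property: rxnorm_id}
    - {kind: identifier, key: mesh_id, node_property: mesh_id}
    - {kind: identifier, key: umls_id, node_property: umls_id}
    - {kind: name, key: name}
sideeffect:
  target: SideEffect
  strategies:
    - {kind: xref, key: meddra_id, xref_table: meddra_umls, node_property: umls_id}
    - {kind: identifier, key: umls_id, node_property: umls_id}
    - {kind: name, key: name}
variant_by_rs:
  target: Variant
  strategies:
    - {kind: identifier, key: rs_id, node_property: rs_id}
pharmacological_class:
  target: PharmacologicalClass
  strategies:
    - {kind: identifier, key: class_id, node_property: identifier}
    - {kind: name, key: name}
bp_by_id:
  target: BiologicalProcess
  strategies:
    - {kind: identifier, key: go_id, node_property: identifier}
cc_by_id:
  target: CellularComponent
  strategies:
    - {kind: identifier, key: go_id, node_property: identifier}
mf_by_id:
  target: MolecularFunction
  strategies:
    - {kind: identifier, key: go_id, node_property: identifier}
cc_by_name:
  target: CellularComponent
  strategies:
    - {kind: name, key: name}
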