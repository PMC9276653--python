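source: ctd
inputs:
  chemicals: {path: ctd_chemicals.tsv, format: tsv}
  chem_gene: {path: ctd_chem_gene.tsv, format: tsv}
  chem_disease: {path: ctd_chem_disease.tsv, format: tsv}
  gene_disease: {path: ctd_gene_disease.tsv, format: tsv}
  chem_go: {path: ctd_chem_go.tsv, format: tsv}
  pathways: {path: ctd_pathways.tsv, format: tsv}
filters:
  - {rule: direct_evidence, input: chem_disease, params: {evidence_column: DirectEvidence}}
  - {rule: direct_evidence, input: gene_disease, params: {evidence_column: DirectEvidence}}
  - {rule: taxon, input: chem_gene, params: {taxon_column: taxon_id, taxon_id: 9606}}
  - {rule: requires_reference, input: chem_gene, params: {reference_column: pubmed_ids}}
emitters:
  - {kind: nodes, label: chemical, input: chemicals}
  - {kind: nodes, label: chem_gene, input: chem_gene}
  - {kind: nodes, label: chem_disease, input: chem_disease}
  - {kind: nodes, label: gene_disease, input: gene_disease}
  - {kind: nodes, label: chem_go, input: chem_go}
  - {kind: nodes, label: pathway_gene, input: pathways}
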