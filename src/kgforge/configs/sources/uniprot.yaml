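source: uniprot
inputs:
  proteins: {path: uniprot_proteins.tsv, format: tsv}
  ppi: {path: uniprot_ppi.tsv, format: tsv}
  disease: {path: uniprot_disease.tsv, format: tsv}
filters:
  - {rule: requires_reference, input: disease, params: {reference_column: pubmed_ids}}
emitters:
  - {kind: nodes, label: protein, input: proteins}
  - {kind: nodes, label: ppi, input: ppi}
  - {kind: nodes, label: disease_assoc, input: disease}
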