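source: drugbank
inputs:
  drugs: {path: drugbank_drugs.tsv, format: tsv}
  structures: {path: drugbank_structures.sdf, format: sdf}
  salts: {path: drugbank_salts.tsv, format: tsv}
  products: {path: drugbank_products.tsv, format: tsv}
  interactions: {path: drugbank_interactions.tsv, format: tsv}
  adr: {path: drugbank_adr.tsv, format: tsv}
  targets: {path: drugbank_targets.tsv, format: tsv}
  atc: {path: drugbank_atc.tsv, format: tsv}
filters:
  - {rule: requires_reference, input: targets, params: {reference_column: pubmed_ids}}
emitters:
  - {kind: nodes, label: drug, input: drugs}
  - {kind: nodes, label: structure, input: structures}
  - {kind: nodes, label: salt, input: salts}
  - {kind: nodes, label: product, input: products}
  - {kind: nodes, label: interaction, input: interactions}
  - {kind: nodes, label: adr, input: adr}
  - {kind: nodes, label: target, input: targets}
  - {kind: nodes, label: atc, input: atc}
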