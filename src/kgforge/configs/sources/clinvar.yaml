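source: clinvar
inputs:
  variation: {path: clinvar_variation.tsv, format: tsv}
  full: {path: clinvar_full.tsv, format: tsv}
  drugs: {path: clinvar_drug_assoc.tsv, format: tsv}
emitters:
  - {kind: nodes, label: variation, input: variation}
  - {kind: nodes, label: full, input: full}
  - {kind: nodes, label: drug_assoc, input: drugs}
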