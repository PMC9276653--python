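source: entrez
inputs:
  main: {path: gene_info.tsv, format: tsv}
filters:
  - {rule: taxon, input: main, params: {taxon_column: tax_id, taxon_id: 9606}}
emitters:
  - kind: nodes
    label: gene
    input: main
    columns: {GeneID: identifier, Symbol: name, Synonyms: synonyms,
              description: description, type_of_gene: type_of_gene,
              tax_id: taxon_id}
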