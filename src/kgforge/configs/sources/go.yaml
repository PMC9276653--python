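source: go
inputs:
  main: {path: go.obo, format: obo}
  annotations:
    path: goa.gaf
    format: gaf
    columns: [db, protein_id, symbol, qualifier, go_id, reference, evidence_code]
emitters:
  - {kind: nodes, label: term, input: main}
  - {kind: nodes, label: is_a, input: "main:edges:is_a"}
  - {kind: nodes, label: annotation, input: annotations}
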