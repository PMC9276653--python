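source: disease_ontology
inputs:
  main: {path: doid.obo, format: obo}
emitters:
  - {kind: nodes, label: term, input: main}
  - {kind: nodes, label: is_a, input: "main:edges:is_a"}
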