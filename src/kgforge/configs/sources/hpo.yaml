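source: hpo
inputs:
  main: {path: hp.obo, format: obo}
  annotations: {path: phenotype.hpoa, format: gaf}
emitters:
  - {kind: nodes, label: term, input: main}
  - {kind: nodes, label: is_a, input: "main:edges:is_a"}
  - {kind: nodes, label: annotation, input: annotations}
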