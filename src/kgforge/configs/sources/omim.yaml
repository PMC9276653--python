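source: omim
inputs:
  entities: {path: omim_entities.tsv, format: tsv}
  edges: {path: omim_edges.tsv, format: tsv}
emitters:
  - {kind: nodes, label: entity, input: entities}
  - {kind: nodes, label: assoc, input: edges}
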