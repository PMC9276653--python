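source: ndfrt
inputs:
  classes: {path: ndfrt_classes.tsv, format: tsv}
  edges: {path: ndfrt_edges.tsv, format: tsv}
emitters:
  - {kind: nodes, label: class, input: classes}
  - {kind: nodes, label: relation, input: edges}
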