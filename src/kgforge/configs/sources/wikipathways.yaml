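source: wikipathways
inputs:
  main: {path: wikipathways.gmt, format: gmt}
emitters:
  - {kind: nodes, label: raw, input: main}
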