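source: pathway_commons
inputs:
  main: {path: pathwaycommons.gmt, format: gmt}
emitters:
  - {kind: nodes, label: raw, input: main}
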