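source: reactome
inputs:
  main: {path: reactome.graphml, format: graphml}
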