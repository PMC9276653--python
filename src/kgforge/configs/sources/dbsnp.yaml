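source: dbsnp
inputs:
  main: {path: dbsnp_rs.tsv, format: tsv}
emitters:
  - {kind: nodes, label: rs, input: main}
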