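source: iid
inputs:
  main: {path: iid_ppi.tsv, format: tsv}
filters:
  - {rule: evidence_contains, input: main,
     params: {evidence_column: evidence_types, token: exp}}
emitters:
  - {kind: nodes, label: ppi, input: main}
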