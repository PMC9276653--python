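source: sider
inputs:
  side_effects: {path: sider_side_effects.tsv, format: tsv}
  causes: {path: sider_causes.tsv, format: tsv}
emitters:
  - {kind: nodes, label: side_effect, input: side_effects}
  - {kind: nodes, label: causes, input: causes}
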