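source: aeolus
inputs:
  outcomes: {path: aeolus_outcomes.tsv, format: tsv}
  pairs: {path: aeolus_pairs.tsv, format: tsv}
filters:
  - {rule: outcome_pairs, input: pairs,
     params: {frequency_column: frequency, count_column: report_count}}
emitters:
  - {kind: nodes, label: outcome, input: outcomes}
  - {kind: nodes, label: pair, input: pairs}
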