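experiment:
  kind: period_sweep
label: cffl1_or
motif:
  edges:
  - source: X
    target: Y
    threshold: 0.1
  - source: X
    target: Z
    threshold: 0.75
  - sense: active_above
    source: Y
    target: Z
    threshold: 0.8
  ffl_type: 1
  gate: OR
  genes:
    Y:
      degradation: 1.0
      synth_off: 0.0
      synth_on: 1.0
    Z:
      degradation: 1.0
      synth_off: 0.0
      synth_on: 1.0
  topology: ffl
signal:
  kind: periodic
  period: 1.0
  profile: symmetric
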