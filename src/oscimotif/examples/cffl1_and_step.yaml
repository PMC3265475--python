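experiment:
  kind: step_response
label: cffl1_and_step
motif:
  edges:
  - source: X
    target: Y
    threshold: 0.5
  - source: X
    target: Z
    threshold: 0.5
  - sense: active_above
    source: Y
    target: Z
    threshold: 0.5
  ffl_type: 1
  gate: AND
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
  kind: step
  level: 1.0
  off_time: 6.0
  on_time: 1.0
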