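# Treatment run aimed at irradiation position P5 (published room/beam defaults).
label: treatment_p5
scenario:
  kind: treatment
  target: P5
  field_size: 10.0
  source_mode: spectrum-beam
run:
  histories: 100000
  batches: 20
  seed: 1
  workers: 1
output:
  directory: results/p5
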