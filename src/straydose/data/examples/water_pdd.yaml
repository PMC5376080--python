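# Water-phantom percent-depth-dose benchmark: SSD 100 cm, 10 x 10 cm2 field,
# 30 cm depth in 0.5 cm bins.
label: water_pdd
scenario:
  kind: water_pdd
  depth: 30.0
  bin_width: 0.5
  field_size: 10.0
run:
  histories: 200000
  batches: 20
  seed: 1
output:
  directory: results/pdd
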