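# Three-organ mini phantom: fast end-to-end exercise of the dose -> F workflow.
label: mini
scenario:
  kind: mini_phantom
  field_size: 3.0
run:
  histories: 10000
  batches: 10
  seed: 1
output:
  directory: results/mini
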