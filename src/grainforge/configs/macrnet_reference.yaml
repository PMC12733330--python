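config:
  image_size: 224
  stem_channels: 64
  stage_channels:
  - 128
  - 256
  - 512
  - 1024
  stage_depths:
  - 2
  - 2
  - 6
  - 5
  width_multiplier: 1.115
  branch_kernels:
  - 1
  - 3
  - 5
  - 7
  - 9
  n_classes: 6
  dropout: 0.2
achieved_params: 8442822
achieved_macs: 4543750272
rel_err_params: 0.00037627279185413216
rel_err_macs: 0.00038535270805812417
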