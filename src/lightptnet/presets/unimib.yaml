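name: unimib
network:
  input_shape: [151, 3]
  n_blocks: 3
  filters: 32
  kernel_sizes: [4, 8, 16]
  dilations: [1, 2, 4]
  dropout: 0.10
  n_classes: 17
  padding: same
  conv_kind: separable
  classifier: gap_softmax
training:
  batch_size: 32
  epochs: 100
  initial_lr: 0.001
  min_lr: 0.0001
  plateau_patience: 3
  plateau_factor: 0.1
data:
  window_length: 151
  channels: 3
  n_classes: 17
  n_subjects: 30
  train_subjects: 21
  test_subjects: 9
  val_fraction: 0.2
  sampling_rate: 50.0
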