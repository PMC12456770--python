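name: wisdm
network:
  input_shape: [200, 3]
  n_blocks: 2
  filters: 40
  kernel_sizes: [4, 8, 12]
  dilations: [1, 2, 4]
  dropout: 0.05
  n_classes: 6
  padding: same
  conv_kind: separable
  classifier: gap_softmax
training:
  batch_size: 64
  epochs: 100
  initial_lr: 0.001
  min_lr: 0.0001
  plateau_patience: 3
  plateau_factor: 0.1
data:
  window_length: 200
  channels: 3
  n_classes: 6
  n_subjects: 36
  train_subjects: 26
  test_subjects: 10
  val_fraction: 0.2
  sampling_rate: 20.0
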