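name: ucihar
network:
  input_shape: [128, 9]
  n_blocks: 2
  filters: 32
  kernel_sizes: [4, 8, 12]
  dilations: [1, 2, 4]
  dropout: 0.05
  n_classes: 6
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
  window_length: 128
  channels: 9
  n_classes: 6
  n_subjects: 30
  train_subjects: 21
  test_subjects: 9
  val_fraction: 0.2
  sampling_rate: 50.0
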