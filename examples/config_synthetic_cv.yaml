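# Example CLI configuration: 10-fold CV of the default DACB model on a
# scaled-down SEED-IV-shaped synthetic corpus (62 channels, 4 classes).
# Run:  dacb cv --config examples/config_synthetic_cv.yaml --out results/
data:
  source: synthetic
  preset: seediv
  spec:
    trial_length: 150
    segment_length: 50
    snr: 10.0
    seed: 11
model:
  n_channels: 62
  n_classes: 4
  seed: 42
train:
  epochs: 3
  batch_size: 1024
  seed: 42
protocol:
  k: 10
  mode: sample_shuffled
  segment_length: 50
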