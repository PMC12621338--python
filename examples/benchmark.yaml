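# Desk-scale synthetic benchmark configuration.
# Every value shown here is the shipped default; the file exists as a
# template for overriding them.
seed: 42

simulate:
  sample_rate: 50.0        # Hz
  reps_per_class: 100
  accel_noise_sd: 0.5      # m/s^2
  gyro_noise_sd: 1.0       # deg/s
  gyro_bias_walk_sd: 0.05  # deg/s per sqrt(s)
  start_offset_max: 200.0  # ms, asynchronous device start-up
  dropout_prob: 0.01
  segment_length_femur: 0.12  # m, sensor lever arm
  segment_length_tibia: 0.10
  cycles_per_recording: 10

sync:
  bin_ms: 100
  max_gap: 3               # bins carried forward before splitting
  window_frames: 30
  stride: 30               # non-overlapping windows

filters:
  accel: {kind: low_pass, cutoff: 2.0, order: 4, zero_phase: true}
  gyro: {kind: high_pass, cutoff: 0.1, order: 2, zero_phase: true}
  per_window: false        # filter whole segments before cutting
  spectrogram_from_raw: false

features:
  segment_length: 8
  hop: 3
  transform_length: 14
  scaling: log1p

model:
  lstm_units: [384, 256]
  lstm_dropout: [0.20, 0.45]
  conv_filters: 128
  conv_kernel: 3
  conv_dropout: 0.40
  cnn_dense_units: 256
  fusion_units: 256
  n_classes: 8
  learning_rate: 0.001
  batch_size: 32
  max_epochs: 50
  early_stop_patience: 8
  branch: fused            # fused | lstm | cnn

split:
  fractions: [0.70, 0.11, 0.19]
  stratified: true
  group_by_recording: true
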