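# The published operating point, written out in full (all values are the
# package defaults; the file exists as a template to copy and edit).
cohort:
  n_mild: 220
  n_severe: 188
  n_features_total: 40
  missing_rate: 0.0
  male_counts: {mild: 188, severe: 157}
fl:
  n_clients: 3
  rounds: 350
  hidden: [32, 16]
  train: {eta: 0.001, epochs: 5, batch_size: 10}
  split: [7, 3]
samples_per_client: 136
missing_threshold: 0.10
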