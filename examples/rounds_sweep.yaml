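# Communication-round sweep at otherwise-default settings.
fl:
  n_clients: 3
  train: {eta: 0.001, epochs: 5, batch_size: 10}
  split: [7, 3]
axis: rounds
axis_values: [10, 50, 150, 350]
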