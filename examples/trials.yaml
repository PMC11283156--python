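# Randomized-trial battery at a reduced round count so 100 end-to-end
# repetitions stay desk-scale; use rounds: 350 for a headline-quality run.
fl:
  n_clients: 3
  rounds: 50
  train: {eta: 0.001, epochs: 5, batch_size: 10}
  split: [7, 3]
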