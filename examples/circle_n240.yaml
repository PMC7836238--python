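# Coverage experiment: smoothed circular phantom, N=240, 95% CSs,
# algorithm 2, scaled-down trial/bootstrap counts for a laptop run.
signal:
  kind: circle2d
  shape: [100, 100]
noise:
  sd: homogeneous
config:
  n_trials: 100
  n_boot: 500
  sample_sizes: [240]
  levels: [0.95]
  algorithms: [2]
  c: 0.8
  seed: 1
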