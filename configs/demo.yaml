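# Small demonstration experiment: 60 promoter-like peaks on a 200 kb
# chromosome, four-timepoint restoration chase, two replicates.
seed: 7
simulation:
  target_chroms: {chr1: 200000}
  spikein_chroms: {spike_2L: 50000}
  n_peaks: 60
  peak_width: 500
  min_gap: 450
  replicated_fraction: 1.0
  background_level: 0.01
  depth: 80000
classify:
  fold_threshold: 1.5
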