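# Desk-scale demo study: 70 transcript contigs, 7 linkage groups of 10
# markers, two RIL populations. All analysis thresholds at their published
# defaults except the panel size, scaled to the candidate pool.
simulation:
  seed: 1
  n_contigs: 70
  n_markers_per_lg: 10
  lg_length_cM: 60.0
  ril_pop_sizes: [80, 60]
thresholds:
  panel_size: 32
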