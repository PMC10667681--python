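temperatures:
- 60.0
- 72.0
- 81.0
- 92.0
probes:
- probe_id: P1-A
  locus_id: P1
  allele: A
  channel: blue
  melt_window: 1
  threshold: 1.075
  tm_final_hairpin: 66.0
  amplitude: 1000.0
- probe_id: P1-B
  locus_id: P1
  allele: B
  channel: blue
  melt_window: 2
  threshold: 1.1
  tm_final_hairpin: 76.5
  amplitude: 1000.0
- probe_id: P2-A
  locus_id: P2
  allele: A
  channel: blue
  melt_window: 3
  threshold: 1.06
  tm_final_hairpin: 86.5
  amplitude: 1000.0
- probe_id: P2-B
  locus_id: P2
  allele: B
  channel: green
  melt_window: 1
  threshold: 1.11
  tm_final_hairpin: 66.0
  amplitude: 1000.0
- probe_id: P3-A
  locus_id: P3
  allele: A
  channel: green
  melt_window: 2
  threshold: 1.08
  tm_final_hairpin: 76.5
  amplitude: 1000.0
- probe_id: P3-B
  locus_id: P3
  allele: B
  channel: green
  melt_window: 3
  threshold: 1.12
  tm_final_hairpin: 86.5
  amplitude: 1000.0
- probe_id: P4-A
  locus_id: P4
  allele: A
  channel: yellow
  melt_window: 1
  threshold: 1.07
  tm_final_hairpin: 66.0
  amplitude: 1000.0
- probe_id: P4-B
  locus_id: P4
  allele: B
  channel: yellow
  melt_window: 2
  threshold: 1.1
  tm_final_hairpin: 76.5
  amplitude: 1000.0
- probe_id: P5-A
  locus_id: P5
  allele: A
  channel: yellow
  melt_window: 3
  threshold: 1.085
  tm_final_hairpin: 86.5
  amplitude: 1000.0
- probe_id: P5-B
  locus_id: P5
  allele: B
  channel: red
  melt_window: 1
  threshold: 1.1
  tm_final_hairpin: 66.0
  amplitude: 1000.0
- probe_id: P6-A
  locus_id: P6
  allele: A
  channel: red
  melt_window: 2
  threshold: 1.08
  tm_final_hairpin: 76.5
  amplitude: 1000.0
- probe_id: P6-B
  locus_id: P6
  allele: B
  channel: red
  melt_window: 3
  threshold: 1.075
  tm_final_hairpin: 86.5
  amplitude: 1000.0
partitions_per_well: 20480
loaded_fraction: 0.9
reaction_volume_uL: 10.0
dna_input_uL: 4.0
normalization:
  window_size: 1001
  statistic: rolling_median
  preliminary_negative_cutoff: 1.0
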