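# Default synthetic study: two streamlined marine pelagic clades versus
# paralog-rich organic-carbon and hydrothermal clades, plus the
# depth-partitioned two-clade niche.  All generator randomness derives
# from `seed`.
seed: 1
clades:
  - clade: marine_I
    n_genomes: 8
    true_genome_size: 1220000
    gc_target: 30.0
    coding_density_target: 96.5
    n_paralog_families: 0
    cn_bias: low_N
  - clade: marine_II
    n_genomes: 8
    true_genome_size: 1220000
    gc_target: 30.0
    coding_density_target: 96.5
    n_paralog_families: 0
    cn_bias: low_N
  - clade: organic_carbon
    n_genomes: 6
    true_genome_size: 3000000
    gc_target: 55.0
    coding_density_target: 88.0
    n_paralog_families: 5
    paralog_copies: 3
    cn_bias: high_N
  - clade: hydrothermal
    n_genomes: 6
    true_genome_size: 2500000
    gc_target: 45.0
    coding_density_target: 90.0
    n_paralog_families: 3
    paralog_copies: 3
    cn_bias: high_N
niche:
  boundary_depth: 100.0
  clade_above: marine_I
  clade_below: marine_II
  dominance: 0.9
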