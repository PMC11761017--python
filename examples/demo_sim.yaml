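# Stand-alone cohort simulation:
#   escape-clock simulate --config examples/demo_sim.yaml --out demo_cohort --seed 1
cancer_types: [TypeA, TypeB, TypeC]
samples_per_type: 10
mean_depth: 100.0
purity_range: [0.6, 0.95]
wgd_probability: 0.5
max_gains_per_segment: 2
n_segments: 10
driver_snvs_per_sample: 5
subclonal_fraction: 0.1
hla_loh_probability: 0.25
gain_posterior_jitter_sd: 0.02
draws_S: 250
pathway_gene_sets:
  early_pathway: [GA1, GA2, GA3, GA4]
  late_pathway: [GB1, GB2, GB3, GB4]
pathway_time_distributions:
  early_pathway: {family: beta, a: 2, b: 8}
  late_pathway: {family: beta, a: 8, b: 2}
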