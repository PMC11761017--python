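# End-to-end demo: simulate a small cohort, time SNVs and HLA LOH,
# classify pathway events against the driver clock, aggregate timelines.
#   escape-clock run --config examples/demo_run.yaml
out_dir: demo_run
seed: 1
S: 100
simulate:
  cancer_types: [TypeA, TypeB]
  samples_per_type: 8
  mean_depth: 80.0
  purity_range: [0.6, 0.95]
  wgd_probability: 0.6
  n_segments: 8
  hla_loh_probability: 0.3
  pathway_gene_sets:
    early_pathway: [GA1, GA2, GA3]
    late_pathway: [GB1, GB2, GB3]
  pathway_time_distributions:
    early_pathway: {family: beta, a: 2, b: 8}
    late_pathway: {family: beta, a: 8, b: 2}
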