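# escape-clock

Posterior timing of somatic mutations on the tumor clonal-evolution
clock, aimed at immune-escape events: when do mutations in
immunomodulatory pathways and HLA loss of heterozygosity (LOH) arise
relative to copy-number gains, whole-genome doubling (WGD) and the bulk
of driver mutations?

The package implements:

- **Gain histories as copy forests** (`escape_clock.forest`): each
  copy-number segment's gain history is a pair of rooted trees of final
  DNA copies (one per parental allele), with gain events as internal
  nodes on a mutation-time axis (0 = conception, 1 = end of the clonal
  period). Posterior draws of gain times (as produced by upstream gain
  timing tools) share one topology per segment.
- **SNV timing** (`escape_clock.timing`): for each SNV, 250 posterior
  timing draws via hierarchical sampling — take a gain-history draw,
  sample a multiplicity state from the read-count posterior
  (`P(state) ∝ prior · Binomial(alt | depth, f)` with
  `f = m·ρ/(n_t·ρ + 2(1−ρ))`), then draw the time uniformly on an edge
  of that multiplicity. Draws sampled as subclonal get the sentinel
  value 1.01.
- **HLA LOH calling and timing** (`escape_clock.loh`): LOH when the
  allelic-imbalance p-value is < 0.01 and the minor-allele copy number
  is < 0.5; in WGD tumors an LOH with minor CN 0 and major CN > 1 is
  placed before the doubling, Uniform(0, t_WGD) per paired draw.
- **Early/late classification** (`escape_clock.classify`): per-sample
  background clock = per-draw mean timing of driver-gene SNVs; an event
  is early (late) when more than 60% of draws put its mean timing below
  (above) the clock. Cancer-type timelines use the smoothed ratio
  `(n_late + 1)/(n_early + 1)` with cutoffs 0.5 / 2, restricted to
  events determined in ≥ 5 samples.
- **Prevalence and pathway selection** (`escape_clock.prevalence`):
  non-synonymous filtering, antigen-presentation-machinery (APM) mutant
  calls (HLA LOH or APM point mutation), oncoprint-style sample×pathway
  matrices, top-regulator selection and cross-study enrichment-frequency
  aggregation.
- **Synthetic cohorts with ground truth** (`escape_clock.simdata`):
  gain forests with optional WGD, planted pathway time distributions,
  binomial read counts at configurable depth, subclonal mixtures, HLA
  LOH events, fabricated gain-timing posterior draws — everything the
  pipeline consumes, plus truth tables to score it.

All tables are plain TSV with 0-based half-open coordinates; SNVs also
round-trip through a minimal VCF. See the docstrings in
`escape_clock.io` for the exact columns.

## CLI

```sh
escape-clock run --config examples/demo_run.yaml      # end to end
escape-clock simulate --config examples/demo_sim.yaml --out demo_cohort --seed 1
escape-clock time-snvs --snvs demo_cohort/snvs.tsv --segments demo_cohort/segments.tsv \
    --gains demo_cohort/gain_posterior.tsv --purity demo_cohort/purity.tsv \
    --draws 250 --seed 1 --out timing.tsv --draws-out timing_draws.tsv
escape-clock time-loh --hla demo_cohort/hla.tsv --gains demo_cohort/gain_posterior.tsv \
    --segments demo_cohort/segments.tsv --purity demo_cohort/purity.tsv --seed 1 --out loh.tsv
escape-clock classify --timing timing.tsv --timing-draws timing_draws.tsv \
    --drivers demo_cohort/drivers.txt --gmt demo_cohort/gene_sets.gmt \
    --purity demo_cohort/purity.tsv --out calls/
escape-clock aggregate --calls calls/calls.tsv --min-samples 5 --out timeline.tsv
escape-clock prevalence --mutations demo_cohort/snvs.tsv --gmt demo_cohort/gene_sets.gmt \
    --purity demo_cohort/purity.tsv --out prevalence/
escape-clock plot-timeline --timeline timeline.tsv --out timeline.png
```

`escape-clock run` exits 0 on success, 2 on config errors, 3 on stage
failures, and writes a manifest recording the seed, all thresholds and
any overrides; reruns with the same config are byte-identical.

## Notes and deliberate simplifications

- Gain-history topology is fixed across posterior draws (noise perturbs
  times only); alternative gain-route uncertainty is out of scope.
- The multiplicity prior defaults to edge time-length (uniform mutation
  arrival per copy); a uniform-over-states prior is available via
  `--prior-mode uniform`. The subclonal prior weight is configurable.
- Per-sample mean timings include the 1.01 subclonal markers by default
  (switchable in the run config).
- Read-level HLA typing/allelic-imbalance estimation and the upstream
  gain-time inference itself are not implemented; their outputs are
  inputs here, and the simulator fabricates them.
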