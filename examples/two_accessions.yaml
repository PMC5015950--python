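# Two accessions observed from one simulated allotetraploid truth:
# 50 genes on one 250-kb chromosome, with injected conversions,
# deletions and silencings.
simulate:
  n_chromosomes: 1
  chromosome_length: 250000
  n_genes: 50
  conversion_genes: 3
  deletion_genes: 2
  silenced_genes: 4
  seed: 11
# the copy-number depth model is normally fitted on hundreds of genes;
# relaxed here for the small example
coverage_min_genes: 30
accessions: [caturra, ar41]
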