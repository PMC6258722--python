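# Packaged demonstration study: a small genome with seven planted eQTL
# effects (five cis, two trans), zero background Hi-C contacts, and a
# control-SNP universe for the Monte Carlo enrichment stage.  With strong
# planted betas and no background every planted pair is recoverable exactly.
seed: 0

simulate:
  genome:
    chromosomes: [[chr1, 400000], [chr2, 300000], [chr3, 300000]]
    fragment_size_mean: 1000
    n_genes: 40
    n_snps: 60
    hla_like_interval: [chr1, 0, 120000]
    gene_length_min: 2000
    gene_length_max: 8000
  tissues: [adipose, artery_tibial, pancreas, skin_lower_leg]
  n_samples: 120
  n_control_snps: 120
  n_cis_effects: 5
  n_trans_effects: 2
  beta: 1.5
  noise_sd: 1.0
  background_rate: 0.0
  maf_range: [0.15, 0.5]

analysis:
  q_threshold: 0.05
  min_count: 1
  min_samples: 70
  fdr_scope: joint
  include_same_fragment: false
  score_threshold: 0.05
  n_sets: 25
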