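{
  "config": {
    "background_genes": null,
    "cis_distance": 1000000,
    "distance_anchor": "tss",
    "fdr_scope": "joint",
    "gmt": null,
    "include_same_fragment": false,
    "inputs": {},
    "min_count": 1,
    "min_samples": 70,
    "n_sets": 25,
    "q_threshold": 0.05,
    "score_threshold": 0.05,
    "seed": 0,
    "simulated": true
  },
  "counts": {
    "n_cis_pairs": 5,
    "n_cis_triples": 20,
    "n_egenes": 7,
    "n_esnps": 7,
    "n_significant_triples": 28,
    "n_tests": 28,
    "n_trans_pairs": 2,
    "n_trans_triples": 8,
    "skipped": {
      "insufficient_samples": 0,
      "monomorphic": 0,
      "unresolved": 0
    }
  },
  "fisher_regulatory_cis_trans": {
    "odds_ratio": null,
    "p_two_sided": 1.0,
    "table": [
      0,
      0,
      5,
      2
    ]
  },
  "ld": {
    "max_r_squared": 0.043529,
    "n_pairs": 21,
    "n_snps": 7,
    "snp_set": "HLA"
  },
  "monte_carlo": {
    "n_sets": 25,
    "null_mean": 0.0,
    "null_sd": 0.0,
    "observed_connections": 7,
    "p_permutation": 0.0384615385,
    "p_value": 0.0,
    "t_statistic": null
  },
  "tissue_contribution": {
    "mean_pct": 14.2857,
    "n_tissues": 4,
    "sd_pct": 0.0
  }
}
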