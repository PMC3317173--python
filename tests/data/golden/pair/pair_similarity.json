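{
  "coding_n": 1287,
  "coding_reason": null,
  "coding_rho": 0.542761,
  "gene_a": "geneA",
  "gene_b": "geneB",
  "length_policy": "resample_min",
  "mode": "coverage",
  "promoter_n": 1000,
  "promoter_reason": null,
  "promoter_rho": -0.010799,
  "resampled": false
}
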