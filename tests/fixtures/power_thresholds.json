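{
  "conditions": {
    "n_genes": 500,
    "n_targets": 20,
    "flank_len": 2000,
    "genome_len": 3000000,
    "rate": 0.002,
    "enrichment": 10.0,
    "alpha": 0.01,
    "n_reps": 5000,
    "seed": 2024
  },
  "min_recall": 20,
  "median_recall": 20,
  "max_false_sig": 5,
  "median_false_sig": 1
}
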