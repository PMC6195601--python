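{
  "sim": {
    "n_peaks": 1500,
    "n_foreground": 1500,
    "n_background": 6000,
    "n_extra_genes": 150
  },
  "n_perm": 50,
  "tiers": [0.01, 0.05, 0.2, 1.0]
}
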