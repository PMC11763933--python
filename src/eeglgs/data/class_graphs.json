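{
  "comment": "Synthetic per-class directed coupling graphs over 19 channels (edges [source, target], 0-indexed). Hand-designed, seed-independent, acyclic (source < target) so the generator VAR stays stable for any coupling strength jitter. Edge sets and densities differ by class so classes are separable by their connectivity structure; the graphs are synthetic stand-ins and carry no physiological claim.",
  "n_channels": 19,
  "graphs": {
    "control": [[0, 1], [2, 3], [4, 5], [6, 7], [8, 9], [10, 11]],
    "schizophrenia": [[0, 2], [1, 3], [2, 4], [3, 5], [4, 6], [5, 7], [0, 8], [1, 9]],
    "depression": [[0, 4], [0, 5], [0, 6], [0, 7], [1, 8], [1, 9], [1, 10], [2, 11], [2, 12], [3, 13], [3, 14], [4, 15]],
    "mci": [[0, 18], [1, 17], [2, 16], [3, 15], [4, 14], [5, 13], [6, 12], [7, 11], [8, 10], [9, 18]],
    "alzheimer": [[5, 6], [6, 8], [8, 10], [10, 12], [12, 14], [14, 16], [16, 18], [7, 9], [9, 11]]
  }
}
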