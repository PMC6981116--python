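{
 "n_cars": 3,
 "n_cars_full_support": 14,
 "true_ancestral_chromosomes": 2,
 "adjacency_recovery": 0.931,
 "n_anchors": 180,
 "inferred_copy_number": {
  "A": 1,
  "B": 1,
  "C": 1
 }
}
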