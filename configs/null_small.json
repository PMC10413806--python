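{
  "p_capture": 0.35,
  "min_exon_reads": 50000,
  "min_mapping_rate": 0.5,
  "fit_bounds": [
    0.001,
    1000.0
  ],
  "min_cells": 40,
  "gof_alpha": 0.01,
  "min_tad_genes": 5,
  "min_boundary_genes": 3,
  "boundary_fraction": 0.05,
  "n_boot": 2000,
  "low_expression_threshold": 2.0,
  "n_random_pairs": 300,
  "window": 9,
  "step": 1,
  "n_tads": 6,
  "genes_per_tad": 8,
  "boundary_genes_per_boundary": 4,
  "n_cells": 80,
  "expression_regime": "well_expressed",
  "share_tad_kon": false,
  "kon_jitter_sigma": 0.0,
  "boundary_coexpr_sigma": 0.0,
  "seed": null
}
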