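# Demo expression workflow: 5-subtype synthetic matrix with planted
# UV-enriched genes and a rod-exclusive rhodopsin-like gene.
# Run: conemosaiq xpr run --config examples/xpr.yaml --out xrun/ --seed 1
seed: 1
expression:
  n_genes: 500
  n_samples_per_subtype: {rod: 6, UV: 5, S: 6, M: 7, L: 6}
  baseline_mean: 50.0
  dispersion: 0.2
  library_size: 1.0e+7
  contamination_fraction: 0.02
  enriched_sets:
    - subtype: UV
      genes: [g00001, g00002, g00003, g00004, g00005]
      fold: 10
    - subtype: rod
      genes: [g00000]
      fold: 50
      exclusive: true
comparisons:
  - {group_a: UV, group_b: S}
  - {group_a: rod, group_b: UV, rod_vs_cone: true}
tf_genes: [g00001, g00002, g00010]
rho_gene: g00000
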