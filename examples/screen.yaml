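# Demo end-to-end screen: a tbx2-like control-vs-mutant cohort.
# Run: conemosaiq screen run --config examples/screen.yaml --out run/ --seed 1
seed: 1
control_group: control
marker: L
cohort:
  mosaic_defaults:
    field_size_um: 64
    px_per_um: 4            # 256 x 256 px; use 16 for the native 1024 px
    n_red_cells: 100
    n_green_only_cells: 1   # bright GFP-only cell anchors the 0-1 range
    cell_radius_um: 2.9
    min_spacing_um: 6.4
    layout: hex
    psf_sigma_px: 1.0
    noise_sd: 10.0
    exact_counts: true
    intensity_params:
      green_only_mean: 3000.0
      green_only_sd: 1.0
      double_mean: 2000.0
      double_sd: 200.0
      baseline_mean: 100.0
      baseline_sd: 20.0
  groups:
    - name: control
      n_fields: 12
      mosaic: {double_positive_fraction: 0.05}
    - name: mutant
      n_fields: 12
      mosaic: {double_positive_fraction: 0.375}
segmentation:
  smooth_sigma_px: 1.0
  min_area_px: 60
quant:
  erosion_radius_px: 10
  alpha: 0.05
stats:
  significance_level: 0.01
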