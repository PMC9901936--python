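# conemosaiq

Quantification toolkit for reporter-based cone photoreceptor screens in
the larval zebrafish retina, with a fully synthetic test bed.

It covers the analysis chain used in F0 (crispant) screens:

- **`synthdata`** — synthetic two-channel retinal fields (jittered cone
  mosaics rendered as blurred disks on a 12-bit detector scale, with
  per-population intensity distributions and ground-truth masks),
  multi-field cohorts, and negative-binomial expression matrices with
  planted enriched gene sets and a tunable rod-contamination mixture.
- **`imaging`** — TIFF I/O for fields and label masks, z-stack maximum
  projection, whole-image 0–1 normalization, a deterministic reference
  segmenter (Gaussian smoothing → Otsu/fixed threshold → connected
  components → optional watershed splitting), and label-wise
  morphological erosion with an emptied-label report. Masks from an
  external segmenter (e.g. Cellpose) can be imported as label TIFFs.
- **`quantify`** — per-cell mean normalized GFP inside eroded marker
  masks (default 10 px disk erosion), control-calibrated
  double-positive thresholds (nearest-rank empirical quantile at
  α = 0.05; the published fixed thresholds L: 0.195 and S: 0.275 are
  available as `fixed_thresholds`), GFP-only counting by overlap
  exclusion, and per-field density summaries (per field and per mm²).
- **`groupstats`** — tie-corrected Kruskal–Wallis, Conover–Iman
  posthoc with Bonferroni adjustment, and group summaries
  (mean ± sd, fold and percent change vs a control group).
- **`xpr`** — FPKM transform, opsin paralog aggregation, the
  differential-expression filter (fold > 1.5, p < 0.01, adjusted
  p < 0.1, positive counts in > 50 % of enriched samples; the fold
  criterion is dropped in rod-vs-cone mode), the transcription-factor
  expression criterion (positive counts in ≥ 20 % of samples), and a
  rhodopsin-based rod-contamination score. Per-gene p-values can be
  ingested from an external count-model package or computed by a
  clearly labelled Welch-on-log2(FPKM+1) stand-in with
  Benjamini–Hochberg adjustment.
- **`cli`** — the `conemosaiq` command with per-stage subcommands and
  YAML-driven end-to-end runs that emit deterministic CSV/JSON reports
  plus a provenance manifest (seed + config hash).

## Command-line usage

```sh
# simulate a field / cohort / expression matrix
conemosaiq simulate field --spec field.yaml --out sim/ --seed 1
conemosaiq simulate cohort --spec cohort.yaml --out sim/ --seed 1
conemosaiq simulate expression --spec xpr.yaml --out sim/ --seed 1

# per-stage tools
conemosaiq segment --in sim/field.tif --channel red --out mask.tif
conemosaiq erode --mask mask.tif --radius 10 --out eroded.tif
conemosaiq quantify --field sim/field.tif --red-mask mask.tif --out quant/

# end-to-end screen (simulate -> segment -> quantify -> compare)
conemosaiq screen run --config screen.yaml --out run/ --seed 1
conemosaiq screen compare --in summaries.csv --metric density_UV --control wt

# expression workflow
conemosaiq xpr run --config xpr_run.yaml --out xrun/ --seed 1
conemosaiq xpr deg --counts c.csv --lengths l.csv --totals t.csv \
    --metadata m.csv --group-a S --group-b M --out deg.csv
conemosaiq xpr contamination --counts c.csv --lengths l.csv \
    --totals t.csv --metadata m.csv --rho rho --out cont.csv
```

Config schemas reject unknown keys, so a typo in a threshold name
aborts the run instead of being silently ignored. Re-running any
pipeline with the same config and seed reproduces outputs byte for
byte.

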