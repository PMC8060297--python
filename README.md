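# panoquant

Quantification and colocalization of immunofluorescence (IF) signals on
whole-section panoramic images, reimplemented as a tested Python library and
CLI. The pipeline works on 8-bit greyscale channel images (DAPI + one marker
per serial section) and covers:

- **image_ops** — pixel primitives: darken/lighten blending (per-pixel
  min/max), inclusive binarization, mask inversion, desaturation (average and
  luminosity modes), five-class dynamic-range heatmaps, and the 750×150
  reference colour step-tablet.
- **morphometry** — whole-section mask construction (lighten-merge →
  threshold at grey value 1 → morphological closing → hole fill),
  epithelial/stromal compartment splitting by mask arithmetic, areas in px
  and mm², compartment fractions, and DAPI-based cellularity.
- **signal_threshold** — the three-stage signal/autofluorescence separation:
  background-floor scan, candidate-threshold scoring by regressing the
  original top-down profile on each binary threshold image's profile
  (highest R² wins), and threshold application.
- **quantify** — 256-bin grey-value histograms with relative counts,
  histogram truncation (246 reported values at a threshold of 10),
  expression domains, calibrated top-down (T-D) plot profiles with
  background-excluded row means, and group tests (Student t-test, one-way
  ANOVA).
- **coloc_models** — stacking per-marker profiles from serial sections,
  simple/multiple OLS with 99% coefficient CIs, 6th-order polynomial
  calibration refinement, virtual knockout (VKO) fold changes, and the
  serial-section compatibility table (reference DAPI profile regressed on
  every stepped section).
- **synthetic_data** — seeded generator of gingiva-like sections with ground
  truth: blob footprint, epithelial boundary band, DAPI speckle, marker
  channels with exact expression domains, a constructed autofluorescence
  floor, shared hotspots, optional embedded weak-signal regions, and serial
  stacks with controllable shape jitter.

## CLI

```bash
panoquant simulate --seed 7 --sections 3 --out sim/         # synthetic data + truth
panoquant morphometry --marker sim/s00_Sdc1.tif --dapi sim/s00_dapi.tif \
    --epithelial-mask sim/s00_epithelial_mask.tif --resolution 0.53937 --out areas.csv
panoquant threshold --image sim/s00_Sdc1.tif --section-mask sim/s00_section_mask.tif
panoquant histogram --image sim/s00_Sdc1.tif --mask sim/s00_section_mask.tif \
    --threshold 10 --out hist.csv
panoquant profile --image sim/s00_Sdc1.tif --mask sim/s00_section_mask.tif \
    --resolution 0.53937 --out profile.csv
panoquant coloc --matrix profiles.csv --dependent CD45 --vko all --out vko.csv
panoquant steptablet --out tablet.png
```

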