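# somatotune

A tested, reusable pipeline from raw measurements to the headline
statistics of a somatosensory tuning study:

- **travelwave** — traveling-wave analysis of digit-cycling fMRI runs:
  lag-shifted gamma-convolved boxcar reference models, voxel-wise
  lag-correlation tuning profiles, sinusoid fits (`y = a·sin(ωx − φ) + B`),
  FDR-thresholded ROI definition, the scalar cortical tuning metric
  (1 / mean period over the ROI), and in-scanner button-press metrics.
- **psychophys** — logistic psychometric fits to temporal-order-judgment
  trial tables and the just-noticeable-difference (JND = slope·ln 3).
- **mrsquant** — spectroscopy QC exclusions (CRLB > 50 %, FWHM > 15 Hz,
  SNR < 40; strict CRLB < 30 % mode), gray-matter partial-volume
  correction, and GABA:Cr / Glu:Cr ratios against tissue-corrected total
  creatine.
- **stats** — Pearson correlations with two-tailed t-based p-values, the
  Hittner (back-transformed-average-z) dependent-correlation comparison,
  first-order partial correlation, the conjunction/omnibus compound test,
  bootstrap mediation (percentile CI, P_M, Sobel Z, Preacher–Kelley κ²),
  and ICC(A,1) with F-based confidence intervals.
- **synthdata** — seed-deterministic generators with known ground truth for
  every raw-data stream: digit-tuned voxel grids (wrapped-Gaussian tuning,
  gamma HRF, optional AR(1) noise), a lapse-capable logistic TOJ observer,
  a structural-equation cohort generator (M = a·X + e, Y = c′·X + b·M + e)
  with a raw-data mode, and metabolite tables with controlled QC failures.
- **pipeline_io** — configuration (YAML), deterministic seed derivation,
  NIfTI/CSV/JSON formats with provenance, and end-to-end orchestration.

## CLI

All functionality is behind one entry point with subcommands:

```sh
somatotune simulate   --out demo/ --seed 1 --n-subjects 12
somatotune tuning     --design design.yaml --forward f.nii.gz --backward b.nii.gz --alpha 0.01
somatotune jnd        --trials trials.csv
somatotune mrs        --table metabolites.csv --qc default
somatotune report     --metrics metrics.csv --boot 5000 --seed 7
somatotune end-to-end --config config.yaml            # or --out out/ --seed 3
```

`design.yaml` holds the task timing (`tr`, `block_s`, `n_cycles`, optional
`digits`, `direction`); trial CSVs have columns `isi_ms` (sign = target
finger first) and `response`; metabolite CSVs have one row per (subject,
metabolite) with `absolute`, `crlb`, `fwhm_hz`, `snr`, `gm`, `wm`, `csf`.
Validation failures exit with code 2, runtime failures with 1.

## Conventions

Voxel indices are 0-based; the lag axis is in seconds within one movement
cycle; ISIs are in milliseconds with positive = target ("middle") finger
stimulated first; all generators take explicit integer seeds and every
pipeline consumer derives its seed deterministically from the global one.
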