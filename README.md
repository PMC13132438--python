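# pneumabio

A multimodal digital-biomarker pipeline for pneumonia mortality analysis,
built entirely around synthetic data with known ground truth. It covers
four analysis branches plus the statistics that tie them to an outcome:

- **`synthdata`** — seeded generators for every input: PQRST sum-of-Gaussian
  ECG traces rendered onto gridded raster pages (25 mm/s, 10 mm/mV),
  Spanish clinical notes with gold criterion labels, lung masks with
  planted activation fractions, and cohort tables with planted per-SD
  logistic effects.
- **`ecg_digitise`** — raster ECG page → calibrated signals: grid
  calibration from projection autocorrelation, grid-suppressed
  intensity-weighted trace centroids, pixel→(ms, mV) conversion, 500 Hz
  resampling, zero-phase 0.5–40 Hz band-pass, TP-segment baseline.
- **`ecg_features`** — Pan-Tompkins R-peak detection, physiological RR
  filtering (300–2000 ms), beat segmentation (−200..+340 ms around R), a
  17-feature morphology registry, group beat templates, and ultra-short
  HRV metrics (MeanNN, SDNN, RMSSD, SD1, SD2, ApEn).
- **`nlp_idsa`** — Spanish text normalisation, dictionary-regex detection
  of the nine modified IDSA/ATS severity criteria (V1) plus context-window
  rules (V2), severity scoring with an age component, and agreement
  statistics (confusion matrices, Cohen's kappa with 95% CI). The matcher
  is purely lexical: a missing keyword can only produce a false negative,
  never a false positive.
- **`cxr_ratio`** — lung splitting (component or midline), per-lung and
  total compromise ratios from an activation map at a strict threshold,
  and LOOCV threshold selection against gold masks (Dice, pixelwise AUROC).
- **`stats_assoc`** — per-SD logistic odds ratios with Wald CIs, Firth
  penalised logistic regression, random-intercept linear mixed models,
  pointwise patient-label permutation tests (exhaustive when feasible),
  Benjamini–Hochberg FDR, Mann-Whitney tests with rank-biserial effect
  sizes, and a table-one builder.
- **`pipeline`** — the end-to-end synthetic study: latent patient factors
  drive both the outcome and the raw modality data; every biomarker is
  re-derived from the rendered inputs and associated with the outcome.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (printed-count
statistics, zero-FP regex property, digitisation round trip, HRV
closed-form oracle, pixel-count oracle, statistical calibration, planted
parameter recovery).

## CLI

One entry point with stage subcommands:

```bash
pneumabio synth ecg --seed 1 --out scratch/ecg              # page + manifest
pneumabio digitise --image page.png --panels manifest.json --out scratch/dig
pneumabio ecg-features --signals scratch/dig --out features.csv
pneumabio synth notes --seed 1 --n 50 --out scratch/notes
pneumabio idsa-score --notes scratch/notes/notes --version v2 --out scores.csv
pneumabio idsa-agree --pred scores.csv --gold scratch/notes/gold.csv
pneumabio synth cam --seed 1 --out scratch/cam
pneumabio cxr-ratio --mask mask.png --cam activation.png --threshold 0.20
pneumabio cxr-loocv --manifest images.csv --grid 0.05:0.95:0.05
pneumabio synth cohort --seed 1 --n 121 --event-rate 0.157 --out cohort.csv
pneumabio assoc or --cohort cohort.csv --outcome outcome
pneumabio assoc perm --templates templates.csv --n-perm 1000 --seed 7
pneumabio run --config run.yaml --seed 1 --out scratch/study
```

`pneumabio run` executes the full synthetic study and writes
`patient_table.csv`, `association.csv`, `permutation.json`,
`agreement.json`, `missingness.csv`, a run manifest and a markdown
summary; identical config and seed give byte-identical outputs.
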