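# ihcscore

Automated quantification of dual-compartment (nuclear/cytoplasmic) DAB
immunohistochemistry on tissue-microarray cores, composite scoring, and the
downstream prognosis statistics — runnable entirely on synthetic data with
known ground truth.

The package covers six stages:

1. **Synthetic data** (`ihcscore.synthetic`) — renders H-DAB-stained TMA
   cores by Beer–Lambert optical-density composition with exact per-pixel
   ground truth (tissue classes, compartments, positivity), and simulates
   patient cohorts with configurable covariate marginals, correlated
   nuclear/cytoplasmic autoscores, duplicate-core noise and
   proportional-hazards survival with a planted changepoint.
2. **Tissue classification** (`ihcscore.classifier`) — a per-pixel
   random-forest over colour + texture features assigning each pixel to one
   of five classes (tumour positive/negative, stroma, lymphocytes,
   background), with pixel-accuracy evaluation against annotation masks.
3. **Stain quantification** (`ihcscore.stain`) — hematoxylin/DAB colour
   deconvolution, nuclear segmentation (Otsu + area filtering), positive
   pixel counts with weak/medium/strong bins per compartment, and
   pseudo-colour mark-up images (nuclei red, cytoplasm orange/yellow).
4. **Scoring** (`ihcscore.scoring`) — autoscores (100 × positive fraction ×
   normalised intensity), the cytoplasmic-to-nuclear ratio (CNR), duplicate
   aggregation by per-measure maximum, evaluability and dichotomisation at
   configurable thresholds (defaults: nuclear autoscore 4.26, CNR 5).
5. **Threshold discovery** (`ihcscore.tree`) — survival decision trees with
   exhaustive log-rank split search and 10-fold cross-validated model
   selection by held-out concordance, plus normalised variable importance.
6. **Cohort statistics** (`ihcscore.stats`) — Pearson χ² association tables,
   Kaplan–Meier / log-rank, Cox proportional hazards (Efron ties, Wald CIs)
   with subgroup filters, and Spearman correlation.

## Command line

Every stage is a verb of the `ihcscore` CLI; results go to files, logs to
stderr:

```bash
ihcscore simulate-images --seed 1 --out out/images --n-cores 20
ihcscore train    --seed 0 --images out/images --out out/model.joblib
ihcscore classify --model out/model.joblib --images out/images --out out/pred
ihcscore quantify --images out/images --labels out/pred --out out/cores.csv
ihcscore score     --cores out/cores.csv --out out/patients.csv
ihcscore simulate-cohort --seed 1 --out out/cohort
ihcscore threshold --seed 0 --cohort out/cohort/patients.csv --out out/tree
ihcscore stats     --cohort out/scored.csv --out out/stats
ihcscore run-all   --seed 1 --out out/full   # full synthetic pipeline
```

`run-all` writes `manifest.json` (seed, versions, per-stage record counts)
alongside all stage artifacts; two runs with the same seed and config are
byte-identical.

### File contracts

- Images: 8-bit RGB PNG/TIFF. Label masks: single-channel PNG with labels
  `{0: background, 1: tumour positive, 2: tumour negative, 3: stroma,
  4: lymphocyte}`.
- Per-core CSV columns: `patient_id, replicate, nuclear_pct,
  nuclear_intensity, cyt_pct, cyt_intensity, nuclear_autoscore,
  cyt_autoscore, cnr, evaluable, tumour_px`.
- Patient-level CSV columns: `patient_id, snas, cytoplasmic_autoscore, cnr,
  evaluable, snas_group, cnr_group` (plus covariate/survival columns when
  merged with a cohort table).
- Configs: YAML or JSON mirroring the dataclass field names
  (`PipelineConfig`, `CohortSimConfig`, `StainParams`,
  `PositivityThresholds`, `ThresholdConfig`).

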