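# eegasym

Hemispheric-asymmetry analysis of multi-channel EEG for emotion
processing, as a tested, reusable pipeline:

1. **Synthetic data** — labeled 62-channel EEG (10-20-extended montage)
   built from band-limited stochastic oscillations plus 1/f background,
   with per-subject variability and *planted* per-band / per-hemisphere /
   per-emotion energy asymmetries whose measured size is calibrated
   against the analysis pipeline itself.
2. **Preprocessing** — polyphase resampling to 200 Hz, zero-phase
   Butterworth band-pass 0.5–50 Hz, non-overlapping 4-s segmentation.
3. **Features** — six-level db2 wavelet decomposition (orthonormal
   periodized transform, exact energy conservation), relative band energy
   per channel for delta/theta/alpha/beta/gamma, and the 135 log-ratio
   asymmetry features over the 27 left/right channel pairs.
4. **Experiment 1** — per (pair, band, emotion) median log energy
   difference, two-sided Wilcoxon signed-rank test of symmetry about
   zero, Bonferroni correction over the full 540-cell family.
5. **Experiment 2** — per emotion, a one-vs-all elastic-net logistic
   regression (no intercept) with ANOVA-F feature screening,
   leave-one-subject-out cross-validation, nested group-aware grid search
   over the l1-ratio × inverse-strength grid, and the eight confusion /
   ranking metrics per fold.
6. **Interpretation** — fold-averaged coefficients, top-5 rankings, and
   expansion of pair-level coefficients into per-channel signed
   association maps (exported as normalized topography tables).
7. **External validation** — the averaged coefficients applied as a
   frozen model (frozen standardization, no refitting) to an independent
   dataset, reported as per-subject AUC-ROC.

## CLI

All stages are exposed as subcommands of `eegasym` (see `--help` on each):

```sh
eegasym simulate   --config config.yaml --out raw/
eegasym preprocess --in raw/manifest.csv --out segments/
eegasym features   --in segments/ --out features.csv
eegasym stats      --features features.csv --alpha 0.05 --out matrix.csv
eegasym train      --features features.csv --emotion sad --out model/
eegasym interpret  --folds model/folds_sad_coefficients.csv --emotion sad --out interp/
eegasym validate   --model model/folds_sad_coefficients.csv \
                   --train-features features.csv --features external.csv \
                   --emotion sad --out val.csv
eegasym run-all    --config config.yaml --seed 1 --out results/
```

`config.yaml` mirrors `eegasym.io.PipelineConfig` (paths, preprocessing
parameters, the model grid, the generator spec for synthetic runs, and a
single seed that fans out deterministically to per-stage child seeds).

Recordings are stored as one `.npz` container per trial plus a
`manifest.csv`; a MATLAB-style `.mat` container holding a `data` variable
(channels × samples) is also accepted. Feature matrices and all results
are plain CSV.

## Layout

```
src/eegasym/
  montage.py     62-label montage, midline set, 27-pair left/right map
  dwt.py         orthonormal periodized db2 wavelet transform
  recording.py   EEGRecording / Segment carriers
  synthetic.py   calibrated synthetic EEG generator with planted effects
  preprocess.py  resample / band-pass / segment
  features.py    relative band energies and log-ratio asymmetry features
  stats.py       Wilcoxon + Bonferroni asymmetry screen (Experiment 1)
  models.py      LOGO-validated one-vs-all elastic-net models (Experiment 2)
  interpret.py   coefficient averaging, ranking, channel expansion
  validate.py    frozen-model transfer to an external dataset
  io.py          readers/writers, config, end-to-end driver
  cli.py         command-line interface
```
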