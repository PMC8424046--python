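# chromacast

Predict the LC-UV chromatogram of a leaf extract from greenhouse sensor
time series.

Per-minute environmental channels (soil pH, soil moisture, ambient
temperature, relative humidity, light intensity) are stochastically
imputed, normalized into [0, 1] with trailing-window technical indicators
(Williams %R, stochastic %K/%D over a grid of window lengths — the data
augmentation), reduced to 128-vectors by piecewise aggregate
approximation, and encoded as 128 x 128 Gramian angular summation or
difference field images.  A small CNN (four 3x3 conv + 2x2 max-pool
stages, two dense layers, MAE loss, RMSProp) maps the five-channel image
tensor to the log-relative-concentration profile y*(t) of the extract's
chromatogram.  Chromatograms are prepared by BEADS baseline correction,
area normalization to a unit-sum relative concentration C(t), and an
invertible log map.  Predictions are scored by lagged cross-correlation,
R², and a peak-matching Matthews correlation coefficient MCC(n) whose
tolerance multiplier n is optimized by scanning f(n) = mu_MCC/sigma_MCC.

A synthetic-data module generates paired environment/chromatogram datasets
with known ground truth (hidden peak table, environment-to-amplitude
weights, solvent masks), so the whole pipeline is testable offline.

## CLI

```sh
chromacast simulate --n-plants 10 --days 30 --seed 1 --out sim/
chromacast ingest manifest.yaml --out store.csv
chromacast impute store.csv --seed 1 --out imputed.csv
chromacast encode imputed.csv --layout 5d --field GASF --out tensors.h5
chromacast prep raw_chromatogram.csv --out prepped.csv
chromacast run config.yaml --run-dir runs/exp1     # simulate->train->evaluate
chromacast evaluate predicted.csv test.csv --n-tolerance 6
```

`chromacast run` consumes a YAML config (see `chromacast.cli.PipelineConfig`
for keys and defaults) and writes per-stage artifacts plus `metrics.json`
into the run directory; stage outputs are keyed by a config hash so
re-running with unchanged training settings reuses the trained model.

## Layout

```
src/chromacast/
  rems_io.py         sensor log ingestion, minute-grid regularization, gaps
  imputation.py      stochastic trend+harmonic regression imputation
  encoding.py        indicators, PAA, GASF/GADF, augmentation, tensors
  chrom_prep.py      BEADS baseline correction, C(t), y*(t) and inverse
  cnn_model.py       the CNN regressor (numpy + numba kernels)
  evaluation.py      xcorr, R², peak matching, MCC(n), tolerance scan,
                     PR-AUC, stratified cross-validation
  synthetic_data.py  ground-truth simulator
  pipeline.py        dataset -> pairs -> model -> metrics glue
  cli.py             click CLI and the YAML-configured runner
```
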