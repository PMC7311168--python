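# ssvep-tuning

Analysis pipeline for frequency-tagged EEG tuning experiments: a synthetic
three-phase differential-conditioning design (habituation, acquisition,
generalization over a six-face morph continuum) with a planted 12 Hz
visuocortical response structure, followed by the full analysis chain —
SCADS-style artifact control, spherical-spline current source density,
spectral signal-to-noise ratios pooled over an occipital cluster, and the
frequentist and Bayesian statistics that consume the resulting SNR tables.

## What is in here

| Module | Purpose |
| --- | --- |
| `ssvep_tuning.design` | pseudo-randomized trial schedules (150 trials, ≤2 repeats in a row, 80%/40% CS+ reinforcement) |
| `ssvep_tuning.subjects` | subject profiles: truncated-normal anxiety scores, ground-truth pattern gain |
| `ssvep_tuning.montage` | 129-channel unit-sphere montages, occipital cluster, sfp I/O |
| `ssvep_tuning.simulate` | epoch synthesis (12 Hz drive + 1/f noise + artifacts), ratings, fast SNR-table simulation |
| `ssvep_tuning.edf` | minimal EDF writer/reader (one data record per epoch) |
| `ssvep_tuning.preprocess` | 40 Hz zero-phase low pass, statistical channel/trial artifact control, spline interpolation, condition averaging |
| `ssvep_tuning.csd` | regularized spherical-spline surface Laplacian (λ added to the trace-normalized Gram diagonal; default λ = 0.2, m = 4, 50 Legendre terms) |
| `ssvep_tuning.spectral` | FFT of the 500–3000 ms window (0.4 Hz bins), SNR = P(12 Hz) / mean of six neighbor bins (±2, ±3, ±4), occipital pooling |
| `ssvep_tuning.stats_lmm` | random-intercept ANCOVA on balanced tables with exact stratum-based denominator df, simple contrasts vs CS−, semi-partial R² with noncentral-F CIs |
| `ssvep_tuning.stats_bayes` | JZS weighted-contrast Bayes factors (M1–M3 vs random-intercept null) by analytic β/σ² integration + Gauss–Legendre quadrature over g, transitive BFs, tuning index, correlation BF, bootstrap BF |
| `ssvep_tuning.pipeline` / `cli` | seeded end-to-end orchestration and staged CLI |

## CLI

End to end from a YAML config (all settings have defaults; see
`ssvep_tuning.pipeline.RunConfig`):

```bash
ssvep-tuning run --seed 7 --out runs/demo
```

writes `snr.csv`, `ratings.csv`, per-phase mixed-model tables
(`lmm_<phase>.csv`), the Bayesian model-comparison table, tuning indices and
their covariate correlations, a bootstrap cross-phase BF, and a manifest
with seeds and checksums. Rerunning the same config reproduces every CSV
byte for byte.

Staged execution over on-disk artifacts (EDF + CSV):

```bash
ssvep-tuning simulate   --config cfg.yaml --out runs/sim
ssvep-tuning preprocess --data-dir runs/sim --out runs/pre --k-iqr 3 --max-bad-channels 20
ssvep-tuning snr        --data-dir runs/pre --montage-dir runs/sim --out runs/snr
ssvep-tuning lmm        --snr-csv runs/snr/snr.csv --ratings-csv runs/sim/ratings.csv --out runs/lmm
ssvep-tuning bayes      --snr-csv runs/snr/snr.csv --out runs/bayes
```

Real data can be substituted at the statistics stages by supplying CSVs with
the documented schemas (`subject_id, phase, condition, snr, spai` and
`subject_id, phase, condition, scale, value, spai`).

## Notes on conventions

- The SNR noise estimate uses six bins, three per side, skipping the two
  immediate neighbors of the driving frequency; spectra are power by default
  (amplitude mode available).
- "Balanced complete" is a contract for the mixed models: missing cells
  raise instead of being dropped, and the denominator df are the exact
  Satterthwaite/Kenward-Roger values for that design
  ((n−2)(c−1) within, n−2 for the covariate).
- JZS prior scales default to r = 0.5 for the shared fixed-effect block and
  r = 1 for the random-intercept block; both are configurable and echoed in
  every result. Each Bayes factor carries a numerical error estimate.
- Bootstrap odds use Laplace smoothing (count+1)/(B−count+1) so finite
  resamples never divide by zero; this is switchable.
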