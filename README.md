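# hvsi

Acoustic scoring of arteriovenous-fistula (AVF) anastomosis sounds for
hemodialysis vascular-access surveillance, plus the surrounding
evaluation machinery:

* **`hvsi.signal_core`** — the 0–999 vascular sound index: STFT
  (Hann, 256 ms, 50 % overlap), 50–1500 Hz band-pass and 300 Hz low-pass
  spectral weighting, rectified time-averaging, and logarithmic
  normalization with explicit calibration constants.
* **`hvsi.hemodynamics`** — Doppler-derived brachial flow volume
  (mL/min) and resistance index from vessel area, velocity–time
  integral, heart rate and systolic/diastolic velocities.
* **`hvsi.bruitsim`** — a seeded generative model of AVF bruits
  (flow-scaled, cardiac-gated band noise) and synthetic case–control
  cohorts, including a fast tabular surrogate sharing the scoring
  calibration, so every downstream stage is testable without clinical
  recordings.
* **`hvsi.diagnostics`** — ROC/AUC (trapezoid ≡ rank statistic, DeLong
  or bootstrap CIs), Youden cutoffs, confusion statistics, concordance,
  and linear association. Test positivity is `score ≤ cutoff`: low
  scores signal reduced flow.
* **`hvsi.cohort`** — propensity-score estimation, greedy 1:1
  nearest-neighbor matching without replacement (0.2 × SD logit
  caliper), covariate balance, and multivariable logistic odds ratios
  with the score scaled per 100 units.
* **`hvsi.io_cli`** — the packaged 20-row verification cohort
  (checksum-pinned), CSV/WAV/YAML I/O and the `hvsi` command line.

## CLI

```bash
hvsi score r1.wav r2.wav r3.wav --json      # score triplicate recordings
hvsi simulate --scenario scen.yaml --out d/ # synthesize bruit WAVs
hvsi cohort --n-cases 101 --n-controls 101 --seed 1 --out cohort.csv
hvsi evaluate cohort.csv --cutoff 121 --reference "fv<400" --json
hvsi roc cohort.csv --reference "fv<500|fv<400|fv<350|group" --stratify bifurcation
hvsi match cohort.csv --covariates age,sex,dialysis_duration,diabetes,crp,past_vaivt
hvsi adjust cohort.csv --outcome "group|fv<400" --step 100
hvsi verify                                  # exact verification-cohort check
```

All commands exit non-zero with a JSON error message on invalid input;
analysis outputs embed the calibration id (and seed where applicable).

## Notes on calibration

The normalization constants of the commercial monitor are not public.
The default calibration (`bruitsim-v1`) is fixed once by
`scripts/tune_calibration.py` so that the simulator's default scenario
spans roughly 41–999 over flows of 160–3025 mL/min; every result records
the `calibration_id` used. Only rank/behavioral fidelity with the
published index is claimed, never numeric equality with device scores.
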