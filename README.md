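# phasesync

Phase-synchrony connectivity analysis for multi-trial, multi-ROI
electrophysiological epochs, exercised end to end on a synthetic data
generator with known ground-truth coupling:

- **synth** — multi-subject epoch generator: 1/f background noise,
  optional stimulus-locked evoked components, band-limited induced
  coupling between ROI pairs with a fixed non-zero phase lag, and
  across-subject covariation between coupling strength and behavioral
  accuracy.
- **preprocess** — baseline correction, amplitude-based trial rejection
  with a CSV log, and trial-count equalization across cells.
- **spectral** — continuous Morlet wavelet transform (default grid:
  8–80 Hz in 3 Hz steps, 25 frequencies; `f/7` cycle schedule), with
  boundary-sample flags.
- **connectivity** — across-trial weighted phase lag index
  (`|Σ Im X| / Σ |Im X|`) per ROI pair × frequency × sample, averaged
  into 10-ms windows over 50–200 ms. Undefined (0/0) values are flagged
  as missing, not reported as 0.
- **surrogate** — trial-shuffle surrogate nulls (trials permuted
  independently per ROI) with add-one empirical p-values.
- **groupstats** — repeated-measures contrasts (2×2 and one-way, each
  `F = t²` with df `(1, n−1)`), post-hoc paired t, Spearman correlation
  with behavior, Benjamini–Hochberg FDR, and signal-detection d′.
- **sem** — lagged path models for effective connectivity: reciprocal
  pairwise fits with trial bootstrap and sign-flip permutation tests,
  plus ML fitting and RMSEA comparison of all 8 unidirectional
  three-node loop models.
- **cli / pipeline** — YAML-configured orchestration of the full chain.

## Tests

```sh
python -m pytest -q
```

The suite includes independent oracles (brute-force FFT convolution for
the wavelet transform, textbook sums-of-squares RM-ANOVA, Pearson-on-
ranks Spearman, analytic implied-covariance SEM recovery) and
Monte-Carlo calibration checks (surrogate type-I rate, directionality
power, volume-conduction robustness).

## CLI

```sh
phasesync simulate   --config config.yaml --out sim/
phasesync preprocess --config config.yaml sim/subject_00.h5 --out clean.h5
phasesync tfr        --config config.yaml clean.h5 --out tf.h5
phasesync wpli       --config config.yaml tf.h5 --out wpli.csv
phasesync surrogate  --config config.yaml tf.h5 --pair AC-lh,vPMC-lh --out sur.csv
phasesync run-all    --config config.yaml --out results/
```

Every stage is a pure function of (inputs, config, seed); `run-all`
writes `syncmap.csv`, `effects.csv`, `surrogate.csv`, optional
`model_ranking.csv`, and a `report.json` with the config hash and seeds.
Omitting `--config` uses the default study-scale configuration
(20 subjects, 2 conditions × 2 stimulus types × 2 tokens × 75 trials,
−200…+500 ms epochs at 1000 Hz).

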