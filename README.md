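# sorsvf — fast visual-field testing by sequentially optimized reconstruction

Standard automated perimetry (SAP) maps an eye's *visual field*: at each of
M = 54 grid locations it estimates the perceived sensitivity (PS, in dB) —
the stimulus attenuation a patient reports seeing 50% of the time.  Because
every estimate costs several noisy button-press trials and patient
reliability decays with fatigue, testing strategies must trade accuracy
against examination length.

`sorsvf` is a simulation and benchmarking library for such strategies,
aimed at vision-science and psychophysics researchers.  It implements:

* **A reconstruction meta-strategy (SORS).**  Visual-field locations are
  strongly correlated, so a complete field can be reconstructed from a
  well-chosen subset of measurements.  Given a training matrix
  `X ∈ R^{M×N}` of complete fields, training greedily selects the ordered
  locations `Ω*_S = (l*_1, …, l*_S)`; at step k each remaining candidate
  `l` is scored by the optimal least-squares basis

      D_k^l = X Y^T (Y Y^T)^{-1},   Y = I_{Ω_{k-1},l} X,

  (`I` the binary selection matrix) and the candidate minimizing
  `‖X − D_k^l Y‖²_F` is appended.  At examination time the locations are
  tested in that order; after k measurements `y` the whole field is
  estimated as `ê_k = D_k y`, and the reconstruction seeds the next
  location's test — as the prior mode of a Bayesian estimator (SORS-Z) or,
  minus a τ = 4 dB offset, as the starting stimulus of an adaptive
  staircase (SORS-D).  Untested locations are reported from the final
  reconstruction.
* **Per-location estimators**: ZEST (Bayesian posterior over integer dB
  values, mixture-of-Gaussians prior, posterior-mean stimulus placement,
  stop at posterior SD < 2 dB or 4 presentations) and a dynamic staircase
  (steps of 4/6/10 dB growing as sensitivity drops, single-reversal
  midpoint estimate).
* **Full-field baselines**: random-order ZEST, the Dynamic Test Strategy
  (DTS, staircases seeded from tested neighbors), and Tendency Oriented
  Perimetry (TOP, exactly one presentation per location).
* **A patient simulator** with a cumulative-Gaussian probability-of-seeing
  curve, threshold-dependent spread `σ(t) = min(exp(−0.081·t + 3.27), 6)`
  dB, and false-positive/false-negative rates (defaults 0.03 / 0.01).
* **A synthetic cohort generator** (spatially correlated fields; healthy
  and glaucoma-like archetypal defects) plus an evaluation harness (RMSE,
  mean deviation, scotoma-border sharpness, patient-wise cross-validation
  folds, test-retest variability, Mann-Whitney comparisons).

## Worked example

`examples/03_single_examination.py` trains the location order on a
synthetic population and examines one unseen glaucomatous patient with
SORS-D (36 of 54 locations) and with DTS:

```
sors-d: 36 locations tested, 94 presentations, RMSE 4.29 dB
   dts: 54 locations tested, 137 presentations, RMSE 3.68 dB
```

The meta-strategy needed ~30% fewer stimulus presentations (a shorter,
less fatiguing examination) at a comparable error against the simulated
ground-truth field.  `examples/04_benchmark_strategies.py` repeats this
over 100 held-out fields and prints per-strategy medians:

```
  strategy  median_rmse  median_presentations   n
       dts     3.191214                 127.0 100
sors-d(36)     3.842234                  96.0 100
sors-z(36)     2.627628                 143.5 100
       top     6.807981                  54.0 100
      zest     3.710584                 212.0 100
```

TOP is fastest but least accurate; full-field ZEST is accurate but long;
the reconstruction meta-strategy shifts the speed–accuracy trade-off.
The other examples cover cohort simulation, training diagnostics and
test-retest variability.

A thin CLI wraps the same functions:

```sh
sorsvf simulate-population --seed 5 --out fields.csv
sorsvf train --input fields.csv --S 36 --out model.json
sorsvf examine --strategy sors-d --model model.json --S 36 \
       --fields fields.csv --index 0 --out exam.json
sorsvf benchmark --cohort fields.csv --model model.json --out results.csv
```

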