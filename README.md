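# aortaflow

Quantification of aortic regurgitation from 2D phase-contrast MR velocity
image series, with transfer of ascending-aorta severity thresholds to the
descending aorta.

The package covers the full chain on fully synthetic data:

* **`aortaflow.synthetic`** — velocity-encoded phantom generator (systolic
  forward / diastolic reversed flow waveforms with controllable regurgitant
  volume and fraction, elliptical lumen cross-sections under plane
  angulation, VENC phase wrapping, planar eddy-current velocity offsets,
  Gaussian velocity noise) and paired patient-cohort simulation from a
  linear ascending-to-descending relation.
* **`aortaflow.flow`** — phase-to-velocity decoding (`v = venc * phi / pi`),
  single-order aliasing unwrap, planar background-offset correction on
  static tissue (0.6 cm/s acceptance limit), threshold-based lumen
  segmentation with phase-to-phase propagation, ROI flow integration, and
  the VENC selection rule (smallest candidate above the expected peak with
  at most 20% headroom).
* **`aortaflow.metrics`** — regurgitant volume (diastolic backward flow
  volume, mL) and fraction (% of the positive flow volume), systolic
  backward flow volume, holodiastolic flow reversal (>= 10 mL/s through
  all of diastole), diastolic flow-reversal velocity (> 19.5 cm/s flag),
  strict-`>` severity calls (42 mL / 33% ascending, 17 mL / 23%
  descending), aortic diameter class (>= 40 mm dilated), and test-retest
  reproducibility.
* **`aortaflow.transfer`** — OLS fit of the descending metric on the
  ascending one (Pearson R with Fisher-z CI, RMSE with n-2 denominator)
  and threshold derivation `slope * reference + intercept` rounded to the
  nearest integer.
* **`aortaflow.diagnostics`** — confusion matrices, sensitivity/specificity
  with Wilson (or exact) CIs, likelihood ratios with log-method CIs,
  Bland-Altman agreement (bias ± 1.96 SD), ROC/AUC by threshold sweep.
* **`aortaflow.pipeline` / `aortaflow.cli`** — configuration, file I/O
  (NPZ/NIfTI phantoms with JSON sidecars, CSV tables, schema-versioned
  JSON reports embedding the config hash and seed) and the CLI.

## CLI

```sh
# simulate a cohort from a built-in generative preset
aortaflow simulate --preset cohort1-rvol --seed 1 --out cohort.csv

# fit the linear relation and derive the descending-aorta threshold
aortaflow fit cohort.csv --out fit.json            # prints derived threshold

# evaluate the derived threshold against the ascending reference
aortaflow evaluate cohort.csv --thresholds fit.json --out eval.json

# render a phantom image series and quantify it
aortaflow simulate --phantom --rvol 45 --reversal holodiastolic \
    --seed 2 --out phantom.npz
aortaflow quantify phantom.json --out curve.csv
aortaflow metrics curve.csv --out metrics.json

# the whole chain in one deterministic run
aortaflow run --seed 1 --out results/
```

## Conventions worth knowing

* Phase values live in `(-pi, pi]`; generator and decoder share the same
  wrap, so decoding below VENC is exact.
* Flow integration uses per-phase Riemann sums with the uniform phase
  duration; systole is `[0, end_systole_index)` where end-systole is the
  first downward zero crossing after the global flow maximum (with
  documented fallbacks).
* All severity comparisons are strict `>` except the diameter class
  (`>= 40 mm` is dilated) and the HFR floor (exactly -10 mL/s counts).
* Cohort draws are untruncated normals: negative values are retained as
  abstract metric values so the generative fit parameters reproduce the
  target correlations.
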