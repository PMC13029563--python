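# dbsbias

Hematocrit (HCT) and blood-volume bias correction for dried blood spot
(DBS) assays.

DBS sampling punches a fixed disc out of a dried drop of capillary
blood and quantifies analytes in it. Two sample properties bias the
result: blood viscosity rises with HCT, so a fixed punch from a
high-HCT spot contains more blood than the calibrators assume, and
converting the measured blood concentration *Cb* to the usually wanted
plasma concentration *Cp* requires the sample's HCT and the analyte's
blood cell-to-plasma partition coefficient *K*:

```
Cp = Cb · Vnom / (Vpred · (1 − HCT + K·HCT))
```

`dbsbias` implements the full correction toolchain for laboratories
and pharmacometricians working with DBS data:

- **estimate HCT** from a spot scan (mean gray value and surface-area
  densitometry) or from hemoglobin absorbance at 550 nm;
- **estimate the blood volume in a punch** from the conductivity of its
  aqueous extract, with per-HCT or pooled calibration curves, plus the
  published surface-area reference model;
- **fit, invert and validate calibration curves** against bioanalytical
  acceptance rules (±15% calibrators, ±20% LLOQ, 85–115% QC accuracy,
  <15% QC RSD);
- **correct Cb to Cp** and quantify the residual error of each
  correction strategy by Monte Carlo propagation of the assays'
  validated accuracy and precision;
- **compare methods** by Deming regression (jackknife CIs),
  Bland–Altman limits of agreement, MPPE/MAPE, and ANCOVA slope
  heterogeneity tests;
- **generate synthetic data** with the study's full response structure,
  so every stage is testable without laboratory data.

See `docs/methods.md` for the models, assumptions and numerical
conventions.

## Worked example

Quantify the residual error of each correction strategy at extreme HCT
for a cell-excluded analyte (K = 0) and an evenly distributed one
(K = 1), with hemoglobin-method HCT noise and conductivity volume
noise:

```python
from dbsbias import run_error_grid

grid = run_error_grid(hcts=(0.2, 0.6), ks=(0.0, 1.0), n_draws=100_000, seed=1)
print(grid.round(2).to_string(index=False))
```

```
 hct   k    strategy  median_rel_err   p2_5  p97_5
 0.2 0.0        none           16.67  16.67  16.67
 0.2 0.0    hct_only          -12.02 -13.07 -10.94
 0.2 0.0 volume_only           37.60   7.99  89.88
 0.2 0.0        both            3.94 -18.50  43.24
 0.2 1.0        none          -12.50 -12.50 -12.50
 0.2 1.0    hct_only          -12.50 -12.50 -12.50
 0.2 1.0 volume_only            3.42 -18.95  42.30
 0.2 1.0        both            3.37 -19.06  42.81
 0.6 0.0        none          -20.83 -20.83 -20.83
 0.6 0.0    hct_only           17.22   0.09  41.24
 0.6 0.0 volume_only          -33.09 -39.21 -25.57
 0.6 0.0        both           -0.75 -17.73  22.81
 0.6 1.0        none           18.75  18.75  18.75
 0.6 1.0    hct_only           18.75  18.75  18.75
 0.6 1.0 volume_only            0.41  -8.81  11.67
 0.6 1.0        both            0.38  -8.85  11.66
```

Each row is one scenario: `median_rel_err` is the median relative
error (%) of the back-calculated plasma concentration over 100,000
Monte Carlo draws, with its 2.5th/97.5th percentiles. Without
correction (`none`) the bias is purely systematic — up to −20.8% at
HCT 0.6 for a cell-excluded analyte — while correcting both HCT and
volume (`both`) pulls every median within a few percent of zero, at
the cost of the assays' measurement noise (the wider percentile
bands).

Calibrating the hemoglobin method on a synthetic five-donor set and
validating it against the acceptance rules:

```python
from dbsbias import DEFAULT_MODELS, DEFAULT_NOISE, DonorSet, generate_calibrators, fit_calibration
from dbsbias.synthesize import generate_qc_replicates
from dbsbias.calibration import validate_calibration

cal = generate_calibrators(DonorSet(seed=1), DEFAULT_MODELS,
                           {"abs": DEFAULT_NOISE["abs"].unbiased()}, modalities=("abs",))
model = fit_calibration(cal[["level", "response"]], "linear", "hct", "abs")
print(model.coefficients, model.r2)   # (1.1379, 0.0024) 0.9758
qc = generate_qc_replicates((0.2, 0.4, 0.6), 5, "abs", DEFAULT_MODELS,
                            DEFAULT_NOISE["abs"], seed=1)
print(validate_calibration(model, cal[["level", "response"]], qc).to_text())
```

```
Calibration validation
======================

LLOQ level: 0.2 (tolerance ±20%)

Calibrator back-calculation (per-level means):
  level 0.2: mean 0.2022 dev +1.08% (tol ±20%) PASS
  level 0.3: mean 0.3064 dev +2.13% (tol ±15%) PASS
  level 0.4: mean 0.3879 dev -3.03% (tol ±15%) PASS
  level 0.5: mean 0.4964 dev -0.71% (tol ±15%) PASS
  level 0.6: mean 0.6071 dev +1.19% (tol ±15%) PASS
QC accuracy / precision:
  level 0.2: accuracy 103.3% RSD 2.71% PASS
  level 0.4: accuracy 100.6% RSD 6.23% PASS
  level 0.6: accuracy 102.9% RSD 8.22% PASS

Overall: PASS
```

The fitted line recovers the generating calibration (slope 1.137) and
all back-calculation, accuracy and precision rules pass at the
published noise levels.

## Command line

The same stages are exposed as subcommands of the `dbsbias` console
script:

```sh
dbsbias simulate --seed 1 --outdir data/          # synthetic inputs
dbsbias calibrate --calibrators data/abs.csv --kind linear --out abs.json
dbsbias measure-spot spot.png                     # MGV + area of one scan
dbsbias estimate --measurements m.csv --models models.json --out est.csv
dbsbias correct --inputs corr.csv --out cp.csv
dbsbias error-grid --seed 1 --out grid.csv --plot grid.png
dbsbias compare --pairs pairs.csv --out agreement.json
dbsbias run --config config.yaml --outdir run/    # full pipeline
```

`run` executes the whole synthetic workflow (generate → calibrate →
estimate → correct → compare → error grid) into a run directory whose
manifest records the config hash, seed and per-file checksums;
identical configs reproduce identical outputs byte for byte.

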