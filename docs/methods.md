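# Methods

`dbsbias` models the two dominant biases of dried blood spot (DBS)
quantification — hematocrit (HCT) and unknown blood volume — and the
measurement methods used to correct them. This note documents the
models, their assumptions, the defaults, the numerical conventions, and
what the synthetic data do and do not demonstrate.

## The bias problem

A DBS assay punches a fixed-diameter disc (6 mm here) out of a dried
spot and reports the analyte concentration in the blood it contains
(Cb). Two properties of the sample confound the quantity usually
wanted, the plasma concentration (Cp):

1. **HCT-based area/volume bias.** Blood viscosity rises with HCT, so
   high-HCT blood spreads less: the spot is smaller and a fixed punch
   contains more blood. A calibrator prepared at HCT 0.4 therefore
   mis-states the volume actually analysed for a patient at HCT 0.2 or
   0.6.
2. **Partition bias.** An analyte distributes between red cells and
   plasma with partition coefficient K. Converting blood to plasma
   concentration requires the sample's HCT:

   `Cp = Cb · Vnom / (Vpred · (1 − HCT + K·HCT))`

   where Vpred is the blood volume actually in the punch and Vnom the
   nominal volume assumed by the calibration. K = 0 means total
   exclusion from cells, K = 1 even distribution (the HCT term cancels),
   K > 1 accumulation in cells.

## Measurement models

All response models are the validated study calibrations, used both as
the generating truth for synthetic data and as the fitting targets:

| quantity | model | role |
| --- | --- | --- |
| mean gray value | MGV = 161.67·HCT² − 237.12·HCT + 177.64 | image-based HCT (darker spot ⇒ higher HCT) |
| spot surface area | SA = −0.0397·HCT + 0.0922 (model units) | image-based HCT via spreading |
| absorbance (550 nm) | ABS = 1.137·HCT + 0.003 | hemoglobin (SLS) HCT |
| punch volume vs conductivity | Vol = slope·Cond + intercept, per HCT level | volume in a 6 mm punch |
| punch volume truth | {0.2: 8.4, 0.3: 9.5, 0.4: 9.6, 0.5: 10.5, 0.6: 11.4} µL, piecewise linear | volume bias truth |

The reference volume model of Alsous et al.,
`SA = 690.414·BV − 72.3·HCT% + 3941.8` with punch SA fixed at 7780, is
implemented as printed algebra (its SA units are unstated); solved for
BV it increases with HCT, consistent with the punch-volume truth table.

### The conductivity curve family is internally inconsistent

The per-HCT volume lines have slopes 25.97, 26.06, 25.18, 23.01, 23.22
but intercepts 10.19, 13.15, −0.01, 29.78, 27.60 µL. Two consequences:

- A single OLS fit through points generated from these five lines gives
  slope ≈ 14 and r² ≈ 0.57 — nothing like the published pooled curve
  (24.7, 16.7, r² = 0.999). The pooled slope does, however, equal the
  arithmetic mean of the per-level slopes to printed precision
  (24.688 → 24.69). The package therefore pools per-level curves by
  averaging their coefficients (`mean_of_level_coefficients`); the OLS
  pooled fit is also exposed and recorded but not used for estimation.
- The intercepts exceed typical punch volumes (~8–11 µL), so inverting
  any of the lines at punch scale yields *negative* conductivities, and
  the smallest calibration volumes (5 µL) invert negative under several
  lines. The generators keep these values, emit a warning, and the
  estimators flag them (`negative-conductivity`), rather than erroring:
  they are the printed calibration algebra, propagated faithfully.

Because a cohort analysed with the average curve must be generated from
the same curve family to be self-consistent, `generate_patient_cohort`
defaults to inverting the mean-of-levels average line; per-HCT
interpolation is available (`conductivity_curve="hct_specific"`) and
exposes how far the printed level lines disagree.

## Synthetic data

The generators emulate the study design: five donors × HCT
{0.2…0.6} calibrator sets, volumetric 20 µL spots, conductivity
calibration over 5–40 µL spotted volumes, and a 23-sample patient-like
cohort with HCT uniform on [0.35, 0.46].

**Noise model.** Measured = true × (accuracy/100) × (1 + ε), with
ε ~ N(0, RSD/100) truncated at ±4 SD (keeps responses positive without
visibly distorting the distribution). Accuracy and RSD anchors are the
published QC values per modality (e.g. hemoglobin: 102.2%/2.45% at HCT
0.2, 95.7%/7.44% at 0.4, 99.1%/5.87% at 0.6) and are interpolated
linearly between anchor levels — the only printed dispersion data.
Calibrators are generated unbiased (accuracy 100%) at the interpolated
RSDs: nominal standards carry no recovery bias; the printed accuracies
describe back-calculation through a fitted curve, which the validation
stage reproduces. QC replicates are generated at the printed accuracy
*and* precision.

**Randomness.** One master seed; each modality (and each Monte Carlo
grid cell) draws from a substream keyed by hashing its name, so
changing one modality's parameters or dropping a grid cell never
perturbs the other streams. Fixed seed ⇒ bitwise-identical tables and
images.

**Spot images.** A spot is rendered as a disc of constant interior
gray (the MGV model value) on a 255 background; a pixel is foreground
iff its center lies inside the disc. The SA model's units are unstated,
so physical area uses a configurable scale anchored so a 20 µL spot at
HCT 0.4 has area 113 mm² (≈12 mm diameter, plausible for this card
type); area scales linearly with spotted volume around the 20 µL
anchor. Pixels are stored as floats in memory (exactness for
noise-free tests); PNG output quantises to 8 bits, which perturbs a
recovered HCT by well under 0.01.

**What the synthetic data do not contain:** drying/oxidation kinetics,
chromatographic ring effects, paper-lot and illumination variability,
multi-spot card layouts, and the LC-MS analyte assay itself (Cb enters
the correction as given). Passing tests therefore demonstrate the
correctness of the estimation and correction machinery under the
published response models and noise magnitudes — not robustness to
those unmodelled effects.

## Calibration and validation

Curves are unweighted OLS (response on predictor), linear or quadratic;
r² = 1 − SSres/SStot, defined as 0 for a constant response. Inverse
prediction inverts the line, or for the quadratic returns the smaller
root — the branch left of the parabola's vertex, where the MGV model is
monotone decreasing on the calibrated range; an HCT inversion with no
root in [0, 1] is an error, and in-range results outside the calibrator
span are flagged rather than rejected (patient samples may fall
slightly outside). Acceptance rules: calibrator per-level mean
back-calculation within ±15% of nominal, ±20% at the LLOQ (defined as
the lowest calibrator level: HCT 0.2, volume 5 µL); QC accuracy within
85–115%; QC RSD (n−1 denominator, bioanalytical convention) below 15%.
A per-replicate judging mode is available behind a flag.

## Monte Carlo error propagation

For each scenario (true HCT × K × correction strategy), the true state
fixes Cp = 1, Cb = 1 − HCT + K·HCT, and the true punch volume from the
punch-volume table. The observed blood concentration is referenced to
the nominal punch volume (at the assumed HCT 0.4, 9.6 µL):
Cb_obs = Cb·V_true/Vnom — this is where the area/volume bias enters an
uncorrected assay. Per draw (100,000 per cell by default):

- measured HCT ~ N(true·acc/100, true·RSD/100) if the strategy corrects
  HCT, else the assumed 0.4; hemoglobin-method noise by default;
- measured volume ~ N(V_true·acc/100, V_true·RSD/100) if the strategy
  corrects volume, else Vnom; conductivity-method noise by default;
- noise anchors are taken from the QC level nearest the true HCT;
- draws outside the physical support (HCT ∉ (0,1), volume ≤ 0) are
  redrawn (truncation);
- relative error = 100·(Cp_est − 1); cells report the median and the
  2.5th/97.5th percentiles (linear interpolation between order
  statistics).

The uncorrected arms set Vpred = Vnom — pure assumption error; sampling
Vpred around the truth instead is available behind
`sample_vpred_when_uncorrected`. This reading makes the
volume-corrected K = 1 case exact up to assay accuracy, matching the
qualitative published result, and the no-correction arm exactly zero at
HCT 0.4.

## Agreement statistics

- **Deming regression**: closed-form moment solution with error-variance
  ratio λ (default 1 — replicate error variances are unknown, so
  orthogonal regression); 95% CIs by leave-one-out jackknife with
  t(n−2) quantiles. Cross-checked in the tests against orthogonal
  distance regression.
- **Bland–Altman**: differences as percent of the pairwise mean by
  default (the acceptance thresholds are relative); LoA = bias ±
  1.96·SD, bias CI via t(n−1)·SD/√n.
- **MPPE / MAPE**: mean signed and mean absolute percent error against
  the reference; MAPE ≥ |MPPE| always.
- **ANCOVA**: response ~ covariate × group, Type III sums of squares
  with sum-to-zero contrasts for the omnibus F tests (the
  sum-of-squares type and coding are a documented package choice);
  per-group slope contrasts vs a reference level t-tested under
  treatment coding. In degenerate noise-free designs a zero-SS effect is
  reported as F = 0, p = 1 instead of 0/0. The study design (5 HCT
  levels × 5 volumes × 6 replicates) yields the F(1, 140)/F(4, 140)
  df structure.

## Workflow and pipeline

`decide_workflow` codifies the decision tree: volumetric samples with
known HCT in the typical band [0.35, 0.46] need no correction; a known
but atypical HCT on a volumetric sample needs the HCT correction only;
any unknown volume requires conductivity-based volume correction, with
HCT taken from the reference value if known, else from the image scan
if present, else from hemoglobin. `run_pipeline` chains generation →
calibration → estimation → correction → agreement → error grid into a
run directory stamped with the config hash and seed; identical configs
reproduce identical bytes. The pipeline estimates cohort volumes with
the average curve (the published choice for the narrow clinical band);
the `auto` policy — average inside the band, nearest HCT-specific curve
outside — remains available but can flip curves for boundary samples
whose noisy HCT estimate strays just outside the band.

## Problem sizes and defaults

Defaults mirror the study design: 5 donors, 5 HCT levels, 5 QC
replicates per level, 23-patient cohorts, 100,000 Monte Carlo draws per
grid cell. The heavier test-suite simulations use 500 replicates
(calibration bias, Deming CI coverage; a 500-sample cohort for the
end-to-end check) and 1000 replicates (ANCOVA type-I error), sizes at
which the binomial/standard-error bands quoted in the tests are
meaningful.

## Known limitations

- Only 6 mm punches; no punch-size scaling model.
- No weighted calibration or heteroscedasticity modelling (the study
  fits are unweighted).
- The conductivity curve family is used as printed despite its internal
  inconsistency (above); absolute punch-scale conductivities are
  physically implausible (negative), though the algebra round-trips.
- The published patient-cohort agreement statistics are not
  reproducible (raw patient data unpublished); agreement methods are
  validated on synthetic cohorts and simulation oracles instead.
- Analytic (delta-method) error propagation is deliberately absent;
  uncertainty is Monte Carlo only.
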