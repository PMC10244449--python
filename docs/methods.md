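# Methods

This note documents the models, numerical choices and limitations behind
`gstride`: the synthetic gait model that serves as ground truth, the
inertial-navigation pipeline, the gait-parameter definitions, the
statistical layer, and the classification experiment. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Synthetic gait model

### Kinematics

The simulator generates a planar sagittal walk of `n_strides` identical
cycles. Each cycle decomposes into four phases whose durations are fixed
fractions of the gait cycle time (GCT):

| phase | default %GCT | foot state |
|---|---|---|
| loading | 11.0 | stationary, pitch blends heel-strike angle → 0 |
| foot-flat | 42.9 | stationary, pitch 0 |
| pushing | 17.8 | stationary, pitch blends 0 → toe-off angle |
| swing | 28.3 | advances one stride length, rises to the clearance apex, pitch blends toe-off → heel-strike angle |

Defaults describe a slow elderly gait: stride length 0.9 m, GCT 1.2 s
(velocity 0.75 m/s, cadence 50 cycles/min), clearance 0.16 m, heel-strike
angle +14.8°, toe-off angle −52.3°, 100 Hz sampling. The four phase
percentages must sum to exactly 100 (the defaults use foot-flat 42.9 so
they do).

All transitions are quintic smoothstep blends `s(u) = 6u⁵ − 15u⁴ + 10u³`,
so position, velocity and acceleration are continuous and *exactly* zero
outside swing; the vertical swing arc is two mirrored quintics meeting at
the apex, which therefore equals the configured clearance exactly. Pitch
reaches its extrema exactly at toe-off and heel strike, making the event
angles well-defined local extrema. Walks start and end with standstills
(defaults 3.5 s and 2.0 s); the leading one provides the attitude/bias
initialisation window and guarantees that the spurious first stance-pair
"stride" exceeds the plausibility window (§4) and is discarded.

Phase durations are snapped to whole samples, the swing to an even count so
the apex lies on a sample. The `GroundTruth` object carries the *realised*
profile (snapped durations, at most one sample from the request per phase);
closure tests compare against the realised values because a sub-sample
phase boundary is not recoverable from sampled data.

The sensor is modelled as a point rigidly attached to the foot: pivoting at
loading and push-off rotates it without translating it. Consequently
loading and pushing are genuine zero-velocity phases in the simulation.
On a real foot the sensor sits a few centimetres from the pivot axes and
translates slightly during these phases; see §7.

### IMU synthesis

Because the kinematics are closed-form, the body angular rate
(ω = (0, −θ̇, 0) for planar pitch θ, toes-up positive) and specific force
(f_b = Rᵀ(a − g), g = (0,0,−9.81) m/s²) are exact. The noise model adds a
constant bias vector (magnitude configurable, direction drawn once per
seed) plus per-sample white noise. Defaults are generic MEMS-grade values —
accelerometer σ = 0.05 m/s², gyro σ = 0.005 rad/s, biases 0.02 m/s² and
0.002 rad/s — chosen once as plausible for a low-cost 6-axis IMU; the
device this emulates does not come with published noise figures, so all
four are config-exposed. Identical seeds give identical recordings.

### Cohort generator

The cohort table emulates a two-group case–control study (default 86
fallers, 77 non-fallers). Every continuous variable — demographics,
clinical scales (GDS, FRG, SPPB, TUG, Short FES-I, 4-m walk time/speed)
and the 17 gait means plus 13 gait STDs — is drawn from a group-specific
normal with configured mean/SD, clipped to its scale range (e.g. FES-I to
[7, 28], SPPB to [0, 12], age ≥ 70) and, for integer scales, rounded.
A single latent "mobility" factor z ~ N(0,1) per subject couples the
variables: each loads with weight λ = 0.6 and the sign of its
non-faller-minus-faller group difference, so gait speed correlates
positively with SPPB and stride length and negatively with TUG and
fear-of-falling, as expected clinically. Categorical variables (sex,
living site, terrain, test site) use group-specific level probabilities.

A full copula was deliberately avoided: only marginal means/SDs and
correlation signs are specified, and one factor reproduces exactly that
structure. BMI is drawn marginally rather than derived from the drawn
weight and height, so the three are mutually consistent only in
distribution, not per subject.

## 2. Stance detection

The detector thresholds a sliding-window average (default 0.1 s) of

    T = w_a (‖a‖ − g)² / σ_a²  +  w_g ‖ω‖² / σ_g²

and marks every sample covered by at least one sub-threshold window as
stationary — the "mark whole passing window" rule keeps boundaries
unbiased, because windows straddling a boundary fail while the last fully
interior window still covers it. The mask is then cleaned by minimum
stance (0.1 s) and swing (0.2 s) durations.

The default weights are w_a = 1, w_g = 0: the angular-rate term is
implemented and config-exposed but disabled. Rationale: the pipeline
defines stance as *zero translation*, and the foot pivots in place at
loading and push-off with rotation rates of the same magnitude as swing
rates, so any effective gyro weight truncates stance to the foot-flat and
destroys the phase decomposition. The magnitude statistic alone separates
translation (‖a‖ deviates from g by tens of m/s² in swing) from rotation
in place (‖a‖ = g exactly for a point sensor). The gyro signal is used
instead where it is informative: the foot-flat sub-interval within stance
is the longest run with ‖ω‖ below 0.05 rad/s (well above the noise floor
of ~0.01, well below loading/pushing rates of 2–8 rad/s).

Zero noise scales are rejected (the statistic is undefined).

## 3. Strapdown and the ZUPT error-state Kalman filter

Orientation propagates by quaternion integration of the midpoint angular
rate; velocity and position integrate trapezoidally. Gravity is the
constant 9.81 m/s² (no latitude model). Quaternions are renormalised each
step.

The filter estimates 9 error states — attitude (navigation frame),
velocity, position — with

    F = I + dt · [[0,0,0], [−[f_nav×],0,0], [0,I,0]],
    Q = diag(σ_g² dt · I, σ_a² dt · I, 0),

(noise-density convention for Q: with Q ∝ dt² the filter becomes
overconfident in its velocity prediction and leaves a several-cm/s
residual stance velocity). At every stance sample the measurement v = 0
with noise 0.01 m/s is applied and the estimated errors fed back
immediately (attitude by `exp(−δθ)`, velocity/position by subtraction);
covariance is symmetrised after each update. Initial attitude comes from
accelerometer levelling over the first quasi-static window (roll/pitch
observable, yaw set to 0 and unobservable throughout — trajectories are
therefore only ever compared through per-stride displacements and path
lengths, never absolute heading). An all-false mask degenerates to the
open-loop strapdown solution with a warning.

**Gyro-bias calibration.** A constant gyro bias is invisible to the
9-state filter: zero-velocity measurements can correct the *current* tilt
but the bias re-tilts the attitude at a constant rate, producing a
steady-state tilt error and a systematic position drift (~13 cm over a
60 s standstill at the default 0.002 rad/s bias, and a linearly growing
pitch error on long walks). Rather than adding bias states — whose
observability over short walks is marginal — the filter estimates the bias
as the per-axis *median* of the angular rate over the quiet samples of the
leading stance and subtracts it (median, because a few low-rate push-off
samples can leak past the quiet threshold and would skew a mean). This is
standard practice for foot-mounted systems, is flagged in the config
(`filter.estimate_gyro_bias`, default on), and reduces the 60 s standstill
drift to under 1 cm.

## 4. Gait events and parameters

Segmentation pairs consecutive stance intervals: heel strike = stance
start, toe-off = stance end, foot-flat = the quiet sub-run (§2), one
stride per stance pair. Parameters per stride:

* **GCT** = t(next HS) − t(HS); the four phase percentages follow from the
  event times and telescope to exactly 100%.
* **Stride length** = horizontal distance between the *mid-foot-flat*
  samples of the bracketing stances. The mid-foot-flat is the
  drift-minimal stance reference (the filter has just been through many
  consecutive zero-velocity updates there).
* **2D/3D paths** = horizontal/3D polyline arc length between those same
  references, clamped to the mathematically guaranteed ordering
  path3d ≥ path2d ≥ SL against floating-point rounding.
* **Clearance** = max height during swing minus the mean foot-flat height
  of the bracketing stances. This is *sensor* clearance: no mounting-height
  offset is subtracted (none is knowable from the data; a config flag can
  apply one).
* **Event angles** = signed pitch extremum within ±3 samples of the event
  (maximum at heel strike, minimum at toe-off; toes-up positive, so
  heel-strike angles are positive and toe-off angles negative). The window
  absorbs detector jitter.
* **Step speed** = mean horizontal speed over the swing samples.

Strides with any phase percentage outside [0, 100] or GCT outside
[0.4, 3] s are flagged implausible and excluded — a physiological filter
that also removes the pseudo-stride spanning the initial standstill.

Walk summaries: total distance = Σ SL, total time = Σ GCT, total steps =
stride count, velocity = Σ SL / Σ GCT (not the mean of per-stride speeds;
the alternative reading is a one-line change), cadence = 60 / mean GCT.
Cadence counts *cycles of the instrumented foot* per minute even though
cohort tables conventionally label the column steps/min; with a single
instrumented foot the two differ by a factor ~2 and the cycle reading is
the one consistent with 60/GCT. Standard deviations use the n−1 form and
are defined as 0 for a single stride.

## 5. Statistical layer

* **Imputation/outliers**: missing cells are filled with the per-variable
  median of the valid cells; physically impossible values (default rule:
  walking speed > 2 m/s) are substituted by the median of the valid cells.
  Every edit is logged (row, variable, old, new) so preprocessing is
  auditable and non-flagged cells are provably untouched.
* **Normality**: one-sample KS against a normal with the sample's mean/SD.
  Since the parameters are estimated, the Lilliefors-corrected p-value is
  the default (the classical KS p, which SPSS-style workflows report, is a
  flag away). Constant vectors are non-normal with p = 0 by convention;
  n ≥ 8 is required.
* **Group comparison**: continuous variables use the Wilcoxon rank-sum
  test (normal approximation, tie and continuity corrected); Student's t
  is available by flag. Categorical variables use Pearson's chi-squared
  *without* Yates continuity correction — the choice is forced by the
  published worked examples this package reproduces (sex counts give
  p = 0.096 → 0.10 uncorrected but 0.137 with Yates).
* **ICC**: single-measure two-way mixed-model consistency,
  ICC(C,1) = (MS_R − MS_E)/(MS_R + (k−1) MS_E), F = MS_R/MS_E with
  df (n−1, (n−1)(k−1)), CI from the F-distribution bounds. Single-measure
  (not average-measure) matches the F(n−1, n−1) degrees of freedom printed
  in the validation literature this mirrors. Consistency ignores fixed
  offsets: ICC(x, x+c) = 1. Perfect agreement (MS_E = 0) returns ICC 1
  with a warning, not an error. Bands: >0.90 very good, 0.71–0.90 good,
  0.51–0.70 moderate, 0.31–0.50 mediocre, else bad/null.
* **Correlations**: per pair, Pearson if both variables pass the normality
  screen, Spearman otherwise; bands on |r|: ≥0.50 strong, ≥0.30 moderate,
  ≥0.10 weak, else null. Constant variables yield an undefined coefficient
  recorded as null with a warning.

Two-sided tests, α = 0.05 throughout. No multiple-testing correction is
applied (none belongs to the workflow being reproduced).

## 6. Faller identification

Features are the 17 walk means plus 13 inter-stride STDs (30 features;
zero-variance columns are dropped with a warning). The classifier is an
RBF-kernel SVM with C = 1 and the `scale` kernel-width heuristic
(1/(n_features · var)); no hyper-parameter search, feature selection or
alternative classifiers are included by design. Evaluation uses 10
repeated random stratified train/test splits with test fraction 0.3 — the
most common reading of "random cross-validation with 10 test sets" — and
the per-split accuracies, their mean and SD are reported. Standardisation
is fitted on the training fold only, and the TUG baseline (faller iff
TUG > threshold; fixed 15 s clinical cutoff by default, or per-split
train-optimised) is evaluated on the *same* splits so the comparison is
paired. The relative improvement is (mean_SVM − mean_TUG)/mean_TUG × 100%.
Accuracy (not balanced accuracy) is the metric; with ~53% faller
prevalence the difference is small.

Leakage is guarded by a property test: with labels randomly permuted, test
accuracy must stay inside the 99% binomial band around chance.

## 7. What the simulator does and does not show

Passing the accuracy suite demonstrates that the estimator chain —
detector, strapdown, filter, segmentation, parameter extraction — is
internally consistent and recovers the parameters of the modelled gait
under MEMS-grade noise across 0.4–1.4 m/s. It does *not* demonstrate
performance on real elderly gait, which additionally exhibits:

* sensor translation during loading/push-off (pivot lever arm), which the
  point-sensor model omits and which would require a gyro-aided or
  ML-based detector rather than the magnitude statistic alone;
* stride-to-stride variability, turning, shuffling, asymmetry and
  non-level ground — the simulator walks straight, identically and on a
  plane (inter-stride STDs of a simulated walk are therefore near zero,
  and cohort-level STD variables are drawn, not processed);
* richer error processes (bias instability, scale-factor error,
  temperature drift) beyond constant bias + white noise.

The clinical variables of the cohort generator reproduce group means/SDs,
ranges and correlation signs, not the full joint distribution of a real
cohort; classification accuracies on it run higher than on real data.

## 8. Pipeline, configuration, reproducibility

`RunConfig` (YAML-serialisable) holds every constant named above; unknown
keys are rejected rather than ignored. The staged runner
(`gstride run -c config.yml`) executes simulate → process → summarize →
stats → classify as configured and writes a manifest (software version,
resolved seeds, per-stage outputs and row counts). All randomness derives
from one top-level seed plus fixed per-stage offsets recorded in the
manifest; re-running a config reproduces the numeric outputs byte-for-byte
(tested).

A pipeline config looks like:

```yaml
pipeline:
  seed: 7
  outdir: out
  stages: [simulate, process, summarize, stats, classify]
  profile: {n_strides: 20, stride_length_m: 0.9, gct_s: 1.2}
  cohort: {n_fallers: 86, n_nonfallers: 77}
run:
  detector: {threshold: 10.0}
  filter: {zupt_noise: 0.01}
```

### Problem sizes

The accuracy suite (`scripts/acceptance.py` and the acceptance tests) uses
50 walks × 20 strides with speeds uniform on 0.4–1.4 m/s, GCT on
1.0–1.4 s, and per-walk randomised phase splits, event angles, clearance
and heading — about 950 scored strides, chosen as the smallest suite that
averages over the profile space while completing in well under a minute.
Property tests run 6–10 random profiles each; the ICC oracle comparison
runs 1000 random 10×2 matrices at 1e-10 agreement.

### Adapting real data

`read_imu_csv` accepts any 7-column log via the column mapping and unit
flags (g → m/s², deg/s → rad/s, ms → s auto-detected by magnitude);
cohort CSVs need the documented clinical column names plus the walk
summary columns. Published open gait databases in that shape can be
processed with the same `process`/`summarize`/`stats` commands; no
downloader is bundled and no result in this repository depends on external
data.
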