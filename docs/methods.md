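# Methods

## Problem setting

Professional drivers accumulate fatigue over a shift; autonomic nervous
activity measured at rest (heart-rate variability, HRV) provides an
objective fatigue readout. The pipeline quantifies sympathetic activation
from short resting beat-interval recordings, indexes daily rear-end
collision risk from automotive warning events, and tests whether post-shift
sympathetic activation predicts the next day's risk exposure.

## HRV analysis

**Input.** Beat-to-beat R-R intervals (RRI, ms) from ~90 s resting
recordings, pre- and post-shift. No R-peak detection is performed; input
starts at intervals.

**Quality control.** A beat is flagged if its interval lies outside
[300, 2000] ms or differs from the previous accepted interval by more than
20%. A recording is rejected when flagged beats exceed 10% of the total;
exactly 10% is accepted (the rejection rule reads "in excess of" the
threshold). Rejected recordings contribute to no downstream statistic.
The comparison against the *previous accepted* interval means a genuine
step change cascades into many flags — intentional, since a step change in
resting RRI within 90 s is itself suspect.

**Spectral estimation.** The interval series is a tachogram sampled
unevenly at the beat times. The default estimator resamples it evenly by
cubic spline at 4 Hz, removes a linear trend, and applies a Hann-windowed
Welch periodogram (segment length 256 samples = 64 s, 50% overlap). Band
powers are trapezoidal integrals of the density over LF = [0.04, 0.15) Hz
and HF = [0.15, 0.40) Hz; bands are half-open so the shared 0.15 Hz edge is
counted once. A Lomb–Scargle estimator working directly on the uneven beat
times is selectable (`SpectralConfig(method="lombscargle")`) as a
sensitivity check; its density normalisation is approximate (peak-integral
calibrated against the sinusoid oracle to ~tens of percent) and it is not
used by default.

On noiseless synthetic recordings with sinusoidal modulation of amplitude
A, integrated band power reproduces the analytic A²/2 to within a few
percent; this is the main numerical oracle of the test suite.

**Indices.** LF/HF is the ratio of band powers (undefined at HF = 0, an
error). The LF deviation score standardises `x = ln(LF / RRI_average)`
against an age-stratified normal reference:
`score = 10 (x − μ_LF(age)) / σ_LF(age) + 50`, i.e. mean 50, SD 10 in the
reference population. The natural logarithm is used throughout. No HF
deviation score is computed (its normative correction is not validated).

**Reference table.** The age-stratified (μ_LF, σ_LF) table is a required
input in 5-year bins with linear interpolation between bin midpoints
(clamped at the ends). The shipped default (`default_norm_table`) is a
**synthetic** design table — mean ln(LF/RRI) declining linearly with age,
constant spread 0.9 ln-units — and doubles as the reference population of
the cohort simulator. It is not a published population norm; users with a
real normative table load it via `NormTable.from_csv`.

## Collision-risk classification

**Features.** Each warning event is a 1 Hz speed trace over the alarm
duration. Features: duration (s); maximum, minimum and mean speed (km/h);
speed deviation (population SD of the samples, km/h); maximum one-second
deceleration (largest consecutive-sample drop, floored at 0). Traces at
other cadences are linearly resampled to 1 Hz first.

**Rule set.** The published rules, read with the CART split convention
(left branch ≤ threshold, so "greater than" is strict and the upper
deviation bound inclusive):

* duration > 79.0 s AND speed deviation in (5.8, 6.5] AND max speed > 39 —
  sustained inter-vehicle warnings at highway speed with intermittent
  acceleration/deceleration;
* duration > 42.5 s AND max speed < 39 — sustained warnings in congested,
  low-speed traffic.

Only example rules were published, not the full tree, so the package treats
this pair as the reference rule set and additionally trains its own CART.

**CART.** `CartRiskClassifier` fits a Gini decision tree with grid search
over max depth {1..6} and minimum leaf size {1, 5, 10}, selected by mean
accuracy over stratified 5-fold cross-validation; folds and tie-breaks are
seeded and recorded in `metadata_`. Class imbalance is left unweighted by
default (configurable via `class_weight`). The fitted tree serialises to
JSON (splits, thresholds, leaf labels) for audit.

**Daily index.** `R` counts risk-classified events per driver-day;
`R_1hr = R / WT` with WT the day's driving hours. Days with WT < 3 h are
flagged excluded and their index withheld from every statistic.

## Association analysis

Records are the inner join of the HRV, daily-risk and VAS streams on
(driver, date); only QC-accepted recordings populate score columns.
"Previous day" means the previous *calendar* date with an accepted
post-shift recording; gaps yield nulls, never carry-forward. Driver-level
exclusions: drivers whose VAS never varies (uninformative self-report) and
drivers with no warning events in the whole study (no risk exposure).

Statistics: Pearson product-moment correlations (two-sided p from the t
distribution with n−2 df, pairwise-complete pairs) of each fatigue index
against `R_1hr`; a median split of `R_1hr` (ties to the low group) compared
by Welch's unequal-variance t-test at α = 0.05, with Shapiro–Wilk p-values
reported per group but never gating the test. No multiple-testing
correction is applied; `results.json` records the number of tests so
readers can apply their own. Repeated measures per driver are pooled
without adjustment — a deliberate simplification matching the target
analysis; a mixed-effects treatment is out of scope.

## Synthetic cohort generator

The generator emulates the study's data streams; its defaults are the
study conditions (33 drivers, 17 shift-days, ages 24–65, ~2 of 33 female,
cross-day correlation 0.29, median daily risk index near 3.2 events/hour).

* **Latent fatigue.** Per driver, a standardised AR(1) chain over the
  measurement occasions pre₁, post₁, pre₂, … with stationary N(0, 1)
  marginals. The post-shift(d) → pre-shift(d+1) step coefficient is
  `rho_crossday` (default 0.29), so the cross-day lag-1 score correlation
  equals it by construction; the within-day pre → post coefficient
  (`rho_withinday`, default 0.5) is a generator convention.
* **Recordings.** The target LF score 50 + 10z is inverted through the same
  norm table the analysis uses to give an LF sinusoid amplitude
  (A = √(2·RRI·e^x)); intervals follow
  `mean + A_LF sin(2π·0.10t) + A_HF sin(2π·0.25t) + N(0, 5 ms)`, emitted
  until 90 s are covered. HF power is lognormal around 300 ms². The daily
  table carries the analytic (truth) scores; the HRV stage recomputes them
  from the emitted beats, agreeing to ≲1 score unit (population SD 10), so
  calibration statements hold for either route.
* **VAS.** Affine in the same-condition LF score (slope 0.8 VAS-points per
  score point, noise SD 10), clipped to [0, 100]. Only the sign of the
  coupling is substantiated by the emulated study; the coefficients are
  conventions.
* **Driving hours.** Lognormal around 8 h (σ = 0.25 ln-units), with a 5%
  chance of a short 1–3 h shift so the exclusion rule is exercised.
* **Events.** Daily risk-event counts are Poisson with rate
  `3.2 · exp(β (LF_post_prev − 50)/10)` per hour — β (`beta_risk`, default
  0.2) is the log-linear fatigue → next-day-risk coupling, and 3.2/h makes
  the median `R_1hr` match the study's split threshold. Non-risk warnings
  arrive at 19.6/h, preserving the ~14% risk share among annotated
  warnings. Label noise (default 0.16) flips emitted annotations,
  mirroring ~84% best achievable held-out accuracy; pre-noise rule labels
  are kept in the truth tables.
* **Event traces.** Speed traces cycle mean, mean+A, mean, mean−A at 1 Hz
  over whole 4 s cycles, so max/min/mean/SD/deceleration are exact
  (SD = A/√2, max deceleration = A). Speeds are integer km/h (quantized
  like vehicle-network speed signals) and durations cluster just past the
  rule thresholds (alarms are mostly short-lived). Together with a
  sampling margin around every rule threshold (1 unit in duration/speed,
  0.1 km/h in speed deviation, configurable down to 0) and disjoint
  oscillation-amplitude bands per event class, this makes the rule
  geometry identifiable: a CART trained on 285 zero-noise events recovers
  the rule labels on essentially all fresh margin-sampled events. The
  margin is enforced on the *extracted* features, with resampling.
* **Reproducibility.** All randomness flows from a single root seed through
  `numpy.random.SeedSequence.spawn` in a fixed stream order (demographics,
  latent fatigue, physiology, VAS, work time, events); identical specs
  reproduce byte-identical tables. `generate_cohort(…, include_rri=False,
  include_events=False)` skips beat- and trace-level synthesis for large
  replicate studies; daily tables and truth are unchanged because scores
  and counts are drawn before any trace is rendered.

**What the generator does not emulate.** Real RRI series have broadband
(1/f-like) spectra, respiration-coupled HF, ectopy and measurement
artefacts — not two clean sinusoids. Real warning events have irregular
speed profiles, and real annotation error is feature-dependent rather than
uniform label flipping. Passing tests therefore demonstrate correctness of
the pipeline's computations and calibration recovery under the assumed
structure, not robustness to field-data pathologies.

## Numerical and design choices

* Welch nperseg is capped at the series length; at 90 s / 4 Hz this gives
  two half-overlapping 64 s segments, a bias/variance compromise that
  keeps the 0.04 Hz band edge resolvable.
* Band integrals interpolate the density at the band edges, making
  contiguous bands exactly additive.
* `evaluate` reports the confusion matrix as predicted × actual, accuracy
  (TP+TN)/N, and the all-warnings baseline precision (actual positives)/N —
  the comparator for the raw sensor.
* The pipeline writes a `manifest.json` (config hash over the scientific
  settings, seed, schema version, per-artifact SHA-256) rather than
  stamping each CSV, keeping the CSV dialects plain.
* Emitted event annotations live in `annotations.csv`; generator truth is
  split across `truth_recordings.csv`, `truth_events.csv` and
  `truth_days.csv`.
* Degenerate inputs raise: empty series (distinct from QC rejection),
  HF = 0 ratios, non-positive LF in the log-score, inverted bands,
  single-class training data, empty evaluation sets, non-positive driving
  hours, degenerate median splits.

## Problem sizes used in the checks

The acceptance script averages 100 replicate cohorts of 33 drivers × 18
days (533 lagged pairs each, ~4 s total). The test suite uses cohorts of
2–60 drivers, 500 score-only replicates for the type-I-error check, and
285/1000-event train/test samples for tree-recovery checks; the full suite
runs in ~20 s on one CPU.

## Known limitations

* The shipped norm table is synthetic; absolute LF scores are only
  meaningful relative to a user-supplied normative distribution.
* The Lomb–Scargle density scaling is approximate; use Welch for
  quantitative band powers.
* Pooled Pearson correlations ignore within-driver correlation of repeated
  measures; p-values are anti-conservative to that extent (the type-I
  check holds at the generator's default dependence structure).
* The published example feature row mixes values from different events (a
  single 13-sample trace cannot have range 53 and SD 6 km/h); it is used
  as a classification example only, not as a reconstructable trace.
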