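# fatiguerisk

Occupational-epidemiology pipeline linking truck-driver autonomic fatigue to
rear-end collision risk. It packages four analysis stages behind one
reproducible workflow:

1. **HRV scoring** (`fatiguerisk.hrv`) — spectral analysis of short (90 s)
   resting RR-interval recordings taken before and after each driving shift.
   Sympathetic tone is summarised by the **LF deviation score**, which removes
   the age and heart-rate dependence of raw low-frequency power:

   ```
   LF_score = 10 · (ln(LF / RRI_average) − μ_LF(age)) / σ_LF(age) + 50
   ```

   with LF the integrated 0.04–0.15 Hz band power (ms²), RRI_average the mean
   beat interval, and (μ_LF, σ_LF) an age-stratified reference table. The
   LF/HF ratio (HF: 0.15–0.40 Hz) is reported alongside. Recordings with more
   than 10% abnormal beats are discarded.
2. **Collision-risk classification** (`fatiguerisk.risk`) — warning events
   from automotive distance sensors are summarised by six vehicle-behaviour
   features (alarm duration; max/min/mean speed; speed deviation; maximum
   1-s deceleration) and classified risk/non-risk either by the published
   rule set (`RuleRiskClassifier`) or by a CART tree fitted to annotated
   events with 5-fold cross-validated grid search (`CartRiskClassifier`,
   scikit-learn estimator API). Daily risk exposure is indexed as
   `R_1hr = R / WT` (risk events per driving hour); days under 3 h of
   driving are excluded.
3. **Association analysis** (`fatiguerisk.association`) — Pearson
   correlations of each fatigue index (VAS, LF score, LF/HF; same-day and
   previous-day post-shift lags) against `R_1hr`, plus a median split of
   `R_1hr` into high/low-risk groups compared by Welch's t-test with
   Shapiro–Wilk normality screening.
4. **Synthetic cohort generator** (`fatiguerisk.synthetic`) — a full study
   simulator (drivers, shift-days, RRI recordings, VAS, driving hours,
   warning events) with the statistical structure the analysis assumes, so
   every stage is testable without field data. Its central calibration is a
   driver-level AR(1) fatigue process giving the post-shift → next-day
   pre-shift LF-score correlation of 0.29.

## Worked example

Run the whole pipeline on a small synthetic cohort (8 drivers × 8 days):

```python
import json
from fatiguerisk.pipeline import PipelineConfig, run_pipeline
from fatiguerisk.synthetic import CohortSpec

cfg = PipelineConfig(
    outdir="example_run",
    seed=1,
    cohort=CohortSpec(n_drivers=8, n_days=8, mean_wt_hours=6.0),
)
run_pipeline(cfg)
print(json.load(open("example_run/results.json")))
```

The run simulates the cohort, scores 128 RRI recordings, classifies 8,471
warning events with a cross-validated CART, builds 61 analysis records and
prints (abridged):

```
"lf_score_post_prev": {"n": 54, "r": 0.625, "p": 4.4e-07}
"lf_hf_pre":          {"n": 61, "r": 0.013, "p": 0.92}
"group_comparison":   {"threshold": 3.29, "n_high": 27, "n_low": 27,
                       "mean_high": 55.08, "mean_low": 47.26,
                       "t": 4.11, "p": 0.00014}
```

Reading: the previous evening's post-shift LF deviation score correlates
positively with the next day's per-hour collision-risk index (r = 0.62 at
this small, strongly coupled setting), the median split at 3.29 events/hour
separates high- from low-risk days by about 8 LF-score points, and Welch's
test calls that difference significant. Same-day correlations are weaker by
construction and noisy at n = 61.

The same workflow is available from the shell:

```bash
fatiguerisk all --outdir example_run --seed 1
fatiguerisk simulate --outdir run2 --seed 3   # or stage by stage
```

Each run directory contains the CSV artifacts (`cohort.csv`, `rri.csv`,
`events.csv`, `hrv.csv`, `daily.csv`, …), `results.json`, diagnostic figures
and a `manifest.json` stamping the config hash, seed and per-file SHA-256.

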