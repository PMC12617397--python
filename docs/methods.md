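# Methods

`hrvequiv` reimplements, as a tested pipeline, an analysis design for
relating resting heart rate variability (HRV) to self-regulation and
psychopathology scores in a pooled multi-country adolescent cohort: adaptive
heart-period artifact correction and RMSSD extraction, derived-item
questionnaire scoring, multilevel multiple imputation, random-intercept
mixed models pooled by Rubin's rules, and two-one-sided-tests (TOST)
equivalence testing against bounds defined as ±5% of each outcome's maximum
score. Because no participant data are available, a synthetic cohort
generator reproduces the statistical structure the analysis assumes, and
every claim the package makes is demonstrated on that generator.

## Heart-period preprocessing

Input is a beat-to-beat interval (RR) series in ms with cumulative
timestamps, as exported by consumer heart-rate loggers. Cleaning proceeds
in a fixed order:

1. **Absolute bounds.** Beats strictly below 300 ms or strictly above
   2000 ms are flagged (boundary values are kept, matching the strict
   inequalities of the rule).
2. **Preliminary RMSSD.** Computed on the bounds-cleaned series. The rule
   personalising the detection threshold needs an HRV estimate before
   detection has run; the bounds-cleaned RMSSD is the only quantity
   available at that point, so it feeds the categorisation.
3. **Norm category.** The preliminary RMSSD is placed against an adolescent
   resting norm (mean 42.9 ms, SD 13.4 ms) with cutoffs at ±1 and ±2 SD;
   categories map to deviation thresholds 0.40 (very low through normal),
   0.45 (high) and 0.50 (very high). Category intervals are left-closed: a
   value exactly at a cutoff takes the higher category. Thresholds are
   monotone in RMSSD, so higher-variability participants are not
   over-corrected.
4. **Local-mean (Karlsson-style) detection.** A beat is flagged when its
   relative deviation from the mean of its nearest non-flagged preceding and
   subsequent beats exceeds the personalised threshold. Passes repeat until
   no new flags appear; flags found within one pass take effect together
   before the next pass (a synchronous update — the order of beats within a
   pass therefore cannot influence the result). Endpoints are compared
   against their single available neighbour. A deliberately naive
   reimplementation that rescans the whole series each iteration is kept in
   the package and asserted equal on randomized corrupted series.
5. **Interpolation.** Flagged beats are replaced by linear interpolation
   between the nearest clean beats in beat-index coordinates (flagged runs at
   either end copy the nearest clean value); series length is unchanged and
   timestamps are recomputed from the corrected intervals.
6. **Quality gate.** A recording is excluded when it has more than 10
   artifacts, spans less than 240 s, or holds fewer than 150 beats. The
   10-artifact rule is the study design's; the duration and beat-count
   gates replace a visual-inspection step with explicit, configurable
   defaults, since reproducibility requires numeric criteria.
7. **Features.** RMSSD = sqrt(mean of squared successive differences over
   the N−1 differences), natural-log RMSSD, mean HR = 60000 / mean(HP),
   minute-wise RMSSD over five consecutive 60-s windows (a beat belongs to
   the window in which it ends), and optionally high-frequency spectral
   power: the tachogram is cubically resampled at 4 Hz, mean-centered, and a
   Welch periodogram is integrated over 0.15–0.40 Hz. The HF estimator
   settings are package choices; no reference settings exist for them.

Known behaviour of the local-mean detector worth stating: a very large spike
inflates the *neighbouring* beats' local means on the first pass, so those
neighbours can be flagged too, and interpolating them removes a little true
variability. Conversely a spike of factor ≈1.5 sitting on an unluckily high
local mean falls just under the 0.40 threshold and is missed (~2% of
factor-1.5 spikes under the default noise level). Both effects bound what
artifact recovery can promise: detection sensitivity ≥ 0.95 and false-flag
rate ≤ 0.02 hold in aggregate, and ~98% of corrupted 300-beat recordings are
restored to within 5% of their pristine RMSSD.

## Questionnaire and task scoring

Three instruments are scored from item tables (0-based response coding, so
instrument maxima are 27, 21, 60 and 24 — consistent with the ±5% bounds
below):

* **Depression (PHQ-A embedded in the 28-item screener):** three symptom
  domains probed by several sub-questions (negative mood: sad/depressed,
  annoyed/irritable, hopeless; sleep: difficulty falling asleep, waking at
  night, sleeping too much; motor: moving slowly, restless) contribute the
  maximum of their constituents; six single items are added; nine domains of
  0–3 give a 0–27 range.
* **Anxiety (GAD-7):** plain sum of seven items (two shared with the
  depression set), 0–21.
* **Screener total:** the published rule is "max of the three sleep items
  plus the sum of all items". Implemented verbatim over a configurable item
  roster. Summing all 28 items implies a maximum of 87, while the
  published ±5% bound of 3.75 implies a 75-point maximum; a 24-item roster
  constant (`MMAPP_TOTAL_ROSTER_75`) reproduces the 75-point scale. The
  discrepancy is documented rather than resolved; equivalence bounds use the
  published values either way.
* **Emotion dysregulation (15-item DERS short form):** three items
  ("pay attention to how you feel", "care about what you are feeling",
  "aware of your emotions") reverse-coded as x → 4−x, then summed, 0–60.
* **Externalizing (8-item DBIS):** plain sum, 0–24.

Task metrics: the go/no-go false-alarm percentage divides responses on no-go
trials by **all** responses (the literal published denominator — not the
no-go trial count) × 100, after dropping practice trials; the delay
discounting immediate-reward percentage divides immediate choices by
responded trials × 100.

Scores are computed only on complete rows; any missing constituent yields
NaN. Totals are re-derived passively after imputation, never imputed
directly.

## Multiple imputation

Chained equations with type-specific conditional models, m = 5 completed
datasets, 10 sweeps by default:

* ordinal items: proportional-odds (cumulative logit) regression, sampling
  coefficients from their asymptotic normal and categories from the implied
  probabilities;
* nominal variables: (multinomial) logistic draws;
* continuous variables: a normal model with country intercepts shrunk by a
  small ridge (1e-5) — a two-level structure represented through penalised
  cluster intercepts — drawing the residual variance from its scaled inverse
  chi-square and coefficients from their normal, then adding residual noise.

The proportional-odds fitter is implemented in the package as a Newton
solver with analytic gradient and Hessian (a tiny ridge, 1e-4, on slopes
keeps near-separated fits bounded; draw covariance is eigenvalue-clipped
with per-direction variance capped at 25, since rare categories leave
thresholds nearly flat and an unbounded draw there is meaningless). It is
asserted against the reference ordered-logit implementation in statsmodels
to 1e-4 in coefficients, standard errors and predicted probabilities; the
dedicated implementation exists because a chained run needs thousands of
such fits.

Predictors use a compact set: log-RMSSD, age, gender, height, weight,
cluster dummies, plus the running mean of the other items of the same
instrument (a summary of the item block). This keeps conditional fits
well-conditioned and fast; a full user-specified predictor matrix is
available through configuration. The visit sequence is ascending
missingness. Failed conditional fits fall back to predictive-mean matching
with 5 donors and are logged. Chains record per-variable mean/SD traces per
sweep. Structurally missing columns (a task not administered at a site) are
excluded from imputation and handled by row omission at analysis time.
log-RMSSD is treated as fully observed: participants without valid HRV are
excluded upstream.

## Mixed models and pooling

Each outcome is regressed on log-RMSSD with age, gender (unordered factor
with all observed levels), BMI and device type as covariates and a random
intercept for country, fitted by REML through statsmodels MixedLM. Because
the optimizer's reported fixed effects can be inconsistent exactly at the
singular boundary (cluster variance → 0), the package recomputes fixed
effects and their covariance from the closed-form GLS expressions at the
REML variance estimates; at the boundary these reduce exactly to OLS.
Random slopes are deliberately not modelled.

Derived quantities:

* **Satterthwaite-type df** per coefficient: 2·f²/Var(f) with
  f = c′Var(β̂)c, the gradient of f in the variance components taken
  numerically, and the variance-component covariance from the closed-form
  expected information of a single-random-intercept model. For
  within-cluster covariates on balanced data this approaches the residual
  df (asserted to within 5% at n ≈ 1000, 3 clusters).
* **ICC** = σ²_country / (σ²_country + σ²_residual).
* **Conditional R²** by the Gaussian variance decomposition
  (var(fixed linear predictor) + σ²_country) / (… + σ²_residual).
* **Rubin's rules** across the m fits: pooled estimate = mean, total
  variance T = W + (1+1/m)·B, with the Barnard–Rubin small-sample df using
  the mean complete-data Satterthwaite df; B = 0 degenerates to the
  complete-data df.
* **Bonferroni**: p_adj = min(1, k·p) with k = 7 pooled tests (6 or 7 per
  country, depending on task availability).

Per-country general linear models use OLS with the same predictors,
dropping factors constant within a country (e.g., device type where a single
device was used).

## Equivalence testing

log-RMSSD is dichotomized at the sample median (ties → Low; the split is
computed once on the complete log-RMSSD, not per imputation). Each outcome
is refit with the group factor (reference = Low, so B > 0 means higher
scores in the High-HRV group), pooled by Rubin's rules, and tested with two
one-sided t tests against bounds ±5% of the outcome's maximum score (3.0,
1.35, 1.05, 3.75, 1.2, and 5.0 for the percentage outcomes):
tL = (B − ΔL)/SE with pL = P(T_df ≥ tL), tU = (B − ΔU)/SE with
pU = P(T_df ≤ tU). Equivalence requires both p < 0.05, which coincides
algebraically with the 90% CI lying inside the bounds; the identity is
asserted on 10,000 randomized draws.

## Synthetic cohort generator

The generator defines the conditions under which every calibration claim is
made. Per participant: country (three sites, default 369 each ≈ 1107),
demographics matched to the cohort's descriptives (age ~14, country-specific
height/weight, ECG chest strap for all of one site and a minority
elsewhere), log-RMSSD Gaussian with mean 3.7175 and SD 0.2958 — chosen so
raw RMSSD has mean ≈ 43 ms and SD ≈ 13 ms, matching the norm reference used
for the artifact thresholds and keeping all threshold categories populated.
A latent outcome is intercept (24) + country intercept (SD 1.4, ICC ≈ 0.02,
inside the 0.01–0.12 range the analysis reports) + β·log-RMSSD (default 0,
the null the study observed) + Gaussian residual (SD 9.5, a DERS-like
scale). Ordinal items arise from the standardized latent trait (loading
0.7 per instrument plus instrument-specific noise) crossing shared
proportional-odds cutpoints, one cutpoint vector per instrument; cutpoint
values are package conventions chosen to give realistic item means, since
no distributional parameters for items are reported anywhere. Task logs
emulate block structure (4 × 30 go/no-go trials, 20 practice; 30
discounting trials), with the go/no-go generated only for the two sites
that administered it. Tachograms combine a 0.25 Hz sinusoidal respiratory
modulation with AR(1) Gaussian beat noise; a helper calibrates noise
amplitude so a recording's expected RMSSD matches the participant's drawn
value. Missingness is MCAR or MAR (logistic in standardized age, overall
rate preserved), writing the categorical missing codes the survey platform
produces and returning a ground-truth mask.

What the generator does *not* emulate: respiratory rate variation and
posture/circadian effects, device-specific beat-detection error,
reaction-time distributions, item residual correlations beyond the single
latent trait, and cultural response styles. Passing tests therefore show
that the pipeline's statistics are correct and calibrated under the stated
data-generating structure, not that real recordings are this clean.

## Calibration studies and problem sizes

Two simulation studies exercise the whole chain (generate → impose MAR
missingness on the continuous outcome and weight at 2%, the magnitude the
survey data showed → impute with m = 5 → fit → pool → test):

* **Type-I error:** β = 0, n = 300 across 3 countries, 1000 replicates;
  the pooled test's rejection rate at α = 0.05 is ~0.047–0.054 across
  pilots (acceptance band 0.03–0.07).
* **Coverage:** β = 2 per log-unit, n = 900, 600 replicates; the pooled
  95% CI covers the truth ~94.3% of the time.

The replicate studies use 5 imputation sweeps instead of the default 10 and
impose missingness on continuous variables only; at 2% missingness the
chains are stationary within 2–3 sweeps, and item-level ordinal imputation
is exercised by its own tests (marginal recovery within ±5 percentage
points under 10% MCAR on a 600-person cohort). These are problem-size
choices for the replicate studies, not changes to the pipeline defaults.

The null-cohort equivalence demonstration runs the full pipeline — including
tachogram simulation and HRV measurement — at n = 3 × 369, m = 5, and checks
the per-outcome equivalence verdicts. One caveat is inherent: with the
analysis's own SE-to-bound margins, a single ~2.5σ draw (on the shared
latent trait or the discounting propensity) defeats one outcome's
equivalence test, so even a true-null cohort shows "all seven equivalent"
only ~93% of the time; the acceptance script averages the verdict count over
three replicate cohorts for that reason.

## Numerical choices and degenerate inputs

Ties at category cutoffs take the higher category; ties at the median split
go Low. Interpolation needs ≥ 2 clean beats, detection ≥ 3 beats, RMSSD ≥ 2
beats; violations raise quality errors rather than returning silent NaNs.
RMSSD = 0 (constant series) leaves log-RMSSD undefined (NaN). Rubin
pooling with zero between-imputation variance returns the complete-data df.
All generators and chains derive their streams from `numpy` SeedSequence
spawns of a single seed; identical configurations reproduce outputs
bit for bit.

## Limitations

The per-coefficient df of the original analysis is approximated, not
reproduced exactly (no reference method is stated for it); the two-level
normal imputation shrinks cluster intercepts with a fixed ridge rather than
sampling a full hierarchical posterior; the compact imputation predictor
set summarises item blocks by their running means instead of entering all
50 items; and equivalence conclusions on synthetic data inherit the
generator's assumptions listed above.
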