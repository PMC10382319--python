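# Methods

## Problem and protocol

The package models a retrospective cohort protocol: preterm infants
(gestational age <32 weeks and/or birth weight <1500 g) are monitored
continuously for their first 30 postnatal days; the binary outcome is
whether they later receive laser coagulation for severe retinopathy of
prematurity (ROP). The cohort is randomly split 1:1 into training and test
sets *before* exclusions are applied (so exclusion counts are reported per
set), and infants are then excluded for gestational age above 32 weeks,
birth weight above 1500 g, or less than 80% monitor-data availability over
postnatal days 1–14. Analysis proceeds in the training set (baseline
table, cluster scan, LOOCV model comparison) with the test set reserved
for one-shot validation of the best models.

## Synthetic data generator

Because clinical monitor exports are not deposited, all simulation-based
validation uses a synthetic cohort generator whose defaults encode the
study conditions: ~15% outcome prevalence, 30-day traces, 60 s sampling
(the monitor export resolution is not standardised, so it is a parameter),
and signed laser-group contrasts in oxygen requirement (FiO2 +1.0 SD, days
5–30), hyperoxia exposure (time >95% SpO2 +0.8 SD, days 5–25),
desaturation incidence (+0.8 SD, days 5–20), heart-rate skewness (−0.8 SD,
days 5–15) and hypoxia burden (time ≤80% and area <80% SpO2, −0.5 SD, days
10–25). Demographics are outcome-correlated: laser infants are drawn
younger (GA ≈ 25.2 ± 1.0 vs 26.9 ± 1.7 weeks) and lighter (birth weight
regressed on GA), with higher rates of inotrope and dexamethasone
exposure.

Signals are built from latent generators:

- **SpO2**: AR(1) around a per-infant setpoint (93 ± 1%, marginal SD 2%,
  autocorrelation timescale fixed across sampling intervals), with
  Poisson desaturation events (rate 4 ± 1.5 per day, depth ≈ 70%, duration
  20 s + Exp(60 s)) and minor ±4% excursions.
- **Heart rate**: AR(1) around 160 ± 7 bpm (SD 5), bradycardia (≈85 bpm)
  and tachycardia (≈210 bpm) plateaus, and minor ±18 bpm excursions whose
  rate and amplitude asymmetry set the daily skewness.
- **FiO2**: a per-infant baseline (0.29 ± 0.04) held in ~4 h steps with
  0.02 step noise, floored at room air (0.21).

Group effects are injected on these latents — never on extracted features —
so feature extraction is genuinely exercised. Effect sizes are specified in
within-group SD units of the targeted daily feature; each family maps to a
latent knob with a scale chosen so one configured SD moves the extracted
feature by about one empirical SD under default parameters. The mapping is
approximate and nonlinear away from |effect| ≈ 1 for the event-driven
families: SpO2 skewness is steered through desaturation depth (its real
physiological driver; additive excursion levers cancel because deep desats
inflate the variance as fast as the third moment), and the
time-≤80% lever acts on desaturation duration, which quantizes to whole
samples and therefore weakens at sampling intervals much coarser than the
default 60 s. Validation of mean-type effects (the calibration and
recovery studies) uses the FiO2 knob, which is linear and
sampling-interval-independent.

What the generator does *not* emulate: ventilator-mode structure,
circadian or care-bundle periodicity, artifact morphology beyond a
validity flag, correlated missingness patterns, and between-centre
heterogeneity. Passing tests therefore demonstrate correctness of the
statistical machinery under a plausible signal model, not clinical
performance on real monitor data.

## Feature extraction

Days are calendar windows [24(d−1), 24d) hours from birth, 1-based.
Invalid samples are excluded everywhere; percentage features use valid
time as the denominator, and a day with no valid samples yields missing
cells (never zeros). Skewness uses the moment estimator
b1 = g1·((n−1)/n)^{3/2} and requires ≥3 samples with non-zero variance.
Hypoxia is counted inclusively (SpO2 ≤ 80%) and hyperoxia strictly
(SpO2 > 95%). Area features use the rectangle rule (sample excess ×
sampling interval), which is exactly testable and indistinguishable from
the trapezoid at 1-min sampling. Event definitions (desaturation
SpO2 <80%, bradycardia <100 bpm, tachycardia >200 bpm, each sustained
≥10 s, runs merged when separated by <10 s) follow standard neonatal
conventions and are fully configurable — they are this package's defaults,
not values attributed to any specific monitor configuration. Events are
assigned to the day containing their onset.

## Cluster permutation test

Pointwise statistic: Welch two-sample t (robust to the 15-vs-85 group
imbalance), missing values dropped day-wise; a day with fewer than two
values in either group gets no statistic and breaks cluster contiguity.
Cluster-forming threshold: the two-sided pointwise critical value at
α = 0.05 with the day's Welch degrees of freedom. Cluster mass: the sum of
t over a maximal same-sign suprathreshold run. Null distribution: the
maximum absolute cluster mass over each of n_perm (default 5000)
group-size-preserving label permutations, pooling both signs — this
controls the family-wise error across days and directions within a
feature. Monte-Carlo p = (1 + #{null ≥ |mass|})/(1 + n_perm), so p is
never below 1/(1+n_perm) and is exact given the seed.

## Classification protocol

Ten feature-set variants: (1) all 13 families × days 1–30; (2) families
with ≥1 significant cluster × days 1–30; (3) the same families restricted
to days 5–15 (a fixed window constant of the protocol); (4) the SF ratio
alone × days 1–30; (5) eight demographic columns; (6) = 3 + demographics;
(7) = 4 + demographics; (8) ten clinical covariates; (9) = 6 + clinical;
(10) = 7 + clinical. Cluster selection picks feature *families*; all days
inside the model's window are then included, which keeps the day-window a
design constant rather than a data-driven quantity inside each fold.

Learner: random forest, 500 trees by default, host-library default split
hyperparameters (none are prescribed by the protocol); the reported
probability is the ensemble-averaged class-1 probability and labels use
probability ≥ threshold (default 0.5). Class imbalance: random
undersampling of the majority class to the minority size, drawn once per
training fold (not per tree) with a fold-specific seed. Missing feature
cells are median-imputed within the training fold only. Per-fold
randomness derives from (master seed, held-out infant id), so LOOCV
predictions are independent of row order and the held-out infant never
influences its own fold's training. Holdout validation trains once on the
full (undersampled) training set; the combined-retrain variant runs LOOCV
over training and test infants pooled. Subgroup analysis repeats the LOOCV
protocol on infants with gestational age ≤28 weeks.

## Evaluation and reporting

Sensitivity, specificity, balanced accuracy (their mean), PPV/NPV, and the
Matthews correlation (0 when any margin is empty; PPV/NPV missing when
undefined). Agresti–Coull 95% intervals are computed on
round(p·n) successes out of n with n defaulting to the total number of
scored subjects — this reconstruction reproduces the published intervals
for sensitivity and specificity at n = 100; the analogous interval for
balanced accuracy (a mean of two proportions, not a binomial proportion)
is reported with the same machinery as a pragmatic approximation. Model
comparison uses the two-sided mid-p McNemar test; b = c = 0 returns p = 1.
Baseline tables use the Wilcoxon rank-sum test for continuous variables
and, for binaries, Fisher's exact test when any expected cell count is
below 5, else the continuity-corrected chi-square (the expected-count rule
is this package's choice; the protocol lists both tests without one).
Report tables round half away from zero at 2 decimals; machine-readable
outputs keep full precision.

## Numerical and design choices

- SF ratio = mean over valid samples of the per-sample ratio
  SpO2[%]/FiO2[fraction] (mean-of-ratios; the alternative ratio-of-means
  differs negligibly at daily aggregation but is not what "per-sample
  oxygenation index" means).
- The 1:1 split uses floor(n/2 + 0.5) training infants; a 269-infant
  cohort splits 135/134.
- Exclusion reasons are assigned with precedence gestational age → birth
  weight → availability, one reason per infant.
- Seed hierarchy: every stage seed is
  SeedSequence([master, stage_tag, extra]) reduced mod 2^31, recorded in
  the run manifest.
- Degenerate inputs: single-class cohorts, empty test sets, overlapping
  train/test ids, zero-length availability windows and invalid event rules
  raise errors rather than returning silently wrong values.

## Problem sizes used in validation

The test suite and acceptance script size the Monte-Carlo studies for a
single CPU: the null-calibration study uses 120–150 null cohorts (n = 100)
at a 300 s sampling interval with 999 permutations each; effect recovery
uses 60–80 seeds (n = 200, +2 SD FiO2 effect on days 5–15); the LOOCV null
uses 20 label permutations of a 60-infant table with 50-tree forests; the
synthetic end-to-end pipeline run uses 120 infants, models 4/5/7, 999
permutations and 150 trees. Calibration of the permutation test is
invariant to the sampling interval (exchangeability of null labels holds
at any resolution), and the FiO2 effect used in the power study is
realized identically at any interval, so the coarser interval changes cost,
not the property under test. Tolerance bands in the tests are 3
Monte-Carlo standard errors at the replication actually used.

## Known limitations

- Realized effect sizes for event-duration and skewness families are
  approximate (±30%) and saturate beyond |effect| ≈ 1.5; the mean-type
  knobs (FiO2, SpO2, HR, SF ratio) are accurate to ~10%.
- The published headline performance of the clinical models is not a
  reproduction target: the clinical data are unavailable and the ensemble
  hyperparameters unreported, so classifier performance on synthetic
  cohorts validates the protocol's machinery, not the clinical effect
  size.
- The balanced-accuracy interval is a binomial approximation (see above).
- No multiple-testing correction is applied across the 13 feature
  families in the cluster scan (family-wise control is within-feature), or
  across the model-comparison McNemar tests — matching the protocol, which
  treats those comparisons as descriptive.
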