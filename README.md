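# ropvitals

Early prediction of severe retinopathy of prematurity (ROP) requiring laser
treatment, from the first postnatal month of routinely monitored
physiological data (SpO2, heart rate, FiO2).

Preterm infants born <32 weeks' gestation and/or <1500 g are screened for
ROP from about 5 weeks of age; risk stratification *before* the first
screening would let clinicians intensify monitoring of high-risk infants
and spare low-risk infants stressful examinations. This package implements
the full analysis protocol for that question as a tested, reusable
pipeline, exercised end to end on a synthetic cohort generator because
clinical monitor data of this kind are not publicly deposited. It is aimed
at researchers in neonatal physiology and clinical prediction modelling who
want to reproduce, probe, or extend the method.

## What it implements

1. **Synthetic cohorts** (`ropvitals.synthetic`) — infants with outcome-
   correlated demographics and 30-day monitor traces built from latent
   generators (per-infant setpoints, AR(1) fluctuations, Poisson event
   overlays). Group effects are injected on the latents in configurable day
   windows, expressed in within-group SD units of the targeted daily
   feature.
2. **Daily features** (`ropvitals.features`) — 13 feature families per
   infant per postnatal day: daily means of SpO2, heart rate, FiO2 and the
   SpO2/FiO2 (SF) ratio; daily skewness of SpO2 and heart rate; hypoxia and
   hyperoxia burden (area and time beyond SpO2 80%/95%); counts of
   desaturations, bradycardias and tachycardias. Invalid samples are
   excluded; empty days yield missing cells.
3. **Cluster permutation testing** (`ropvitals.cluster`) — the
   non-parametric cluster-mass procedure for longitudinal group
   comparisons: per-day Welch t statistics, suprathreshold runs summed into
   cluster masses, and a permutation null of the maximum absolute cluster
   mass, giving family-wise-corrected Monte-Carlo p-values per feature.
4. **Classification protocol** (`ropvitals.classify`) — ten feature-set
   variants (physiological × day-window, demographics, clinical covariates)
   trained as random forests with random undersampling inside every
   leave-one-out fold, ensemble-averaged probabilities, threshold sweeps,
   independent-test validation and gestational-age subgroup retraining.
5. **Evaluation metrics** (`ropvitals.metrics`) — balanced accuracy,
   sensitivity, specificity, MCC, predictive values; Agresti–Coull 95%
   intervals; two-sided mid-p McNemar model comparisons; ROC staircases;
   and the baseline demographics table (rank-sum / chi-square / Fisher).
6. **Pipeline + CLI** (`ropvitals.pipeline`, `ropvitals` command) —
   simulate → 1:1 split (before exclusions) → inclusion filter (GA ≤ 32
   weeks, BW ≤ 1500 g, ≥80% data availability over days 1–14) → features →
   baseline table → cluster scan → train/evaluate/validate, with a seed
   hierarchy that makes every stage independently reproducible.

## The statistics at the core

For a feature family observed on days $d = 1..30$, the cluster-mass
statistic of a run $C$ of consecutive suprathreshold days is
$m(C) = \sum_{d \in C} t_d$, where $t_d$ is the Welch two-sample statistic
comparing laser vs non-laser infants on day $d$ and a day is suprathreshold
when $|t_d|$ exceeds the two-sided pointwise critical value at α = 0.05.
Group labels are permuted (sizes preserved); each permutation contributes
$\max_C |m(C)|$ to the null, and an observed cluster is reported with
$p = (1 + \#\{\text{null} \ge |m|\})/(1 + n_{\text{perm}})$.

Classification handles the ~15% outcome prevalence by undersampling: in
every training set the majority class is randomly reduced to the minority
size before fitting the forest. Reported uncertainty uses the
Agresti–Coull interval for a proportion $\hat p = k/n$:
$\tilde n = n + z^2$, $\tilde p = (k + z^2/2)/\tilde n$,
$\tilde p \pm z\sqrt{\tilde p(1-\tilde p)/\tilde n}$. Models are compared
with the two-sided mid-p McNemar test on discordant pairs $(b, c)$:
$p = 2P(X \ge \max(b,c)) - P(X = \max(b,c))$, $X \sim \text{Bin}(b+c, 1/2)$.

## Worked example

```bash
python examples/05_metrics_worked_example.py
```

prints, for a model detecting 11 of 15 laser infants with 10 false alarms
among 85 (a reconstruction of the strongest training-set model):

```
sensitivity        0.73  (0.64-0.81)
specificity        0.88  (0.80-0.93)
balanced accuracy  0.81
MCC                0.54
PPV / NPV          0.52 / 0.95

mid-p McNemar, discordant pairs (5, 1): p = 0.125
```

The intervals are Agresti–Coull 95% bounds at n = 100; the McNemar p-value
says 5-vs-1 discordant classifications are compatible with chance. The
other examples (`examples/01`–`04`) walk through cohort simulation, feature
extraction, the cluster scan, and LOOCV model comparison; each prints the
numbers it computes with a comment on what they mean. The full pipeline
runs as `ropvitals all --out run_dir --seed 1` (or stage by stage via
`simulate`, `extract-features`, `clusterscan`, `train-eval`, `report`).
The default configuration simulates the full study scale (269 infants, ten
models, 5000 permutations, 500 trees) and takes a while on one core; a
YAML config passed with `--config` scales any of it down (see
`RunConfig`).

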