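# Methods

## Problem and model

`mirvote` implements an ensemble-vote classifier for recurrence risk in
lymph-node-negative breast cancer from miRNA expression profiles. The study
design it targets is a matched case-control cohort: each *case* (a patient
with regional or distant metastasis within 120 months of surgery) is paired
with a *control* (a recurrence-free patient with long follow-up) matched on
clinical covariates — tumor type, ER status, grade exactly; age, tumor size
and year of surgery within calipers. Matching removes the classical clinical
markers as confounders, so any classification signal must come from
expression.

Seven classification methods each cast one binary vote per patient
(1 = predicted recurrence):

| Method | Model | Vote rule |
|---|---|---|
| RSVM | RBF-kernel SVM, Platt-scaled | p(recurrence) ≥ 0.5 |
| RF | random forest, 500 trees | p ≥ 0.5 |
| NB | Gaussian naive Bayes | p ≥ 0.5 |
| LSVM | linear SVM, Platt-scaled | p ≥ 0.5 |
| COX-RS | univariate Cox risk sums | risk sum > training median |
| KNN | k-nearest neighbors, k = 5 | predicted class |
| LR | ridge logistic regression | p ≥ 0.5 |

A patient's vote count (0–7) is cut into risk groups: **ultralow** (0 votes),
**low** (0–1 votes), **high** (otherwise). A dataset-adaptive (`auto`) rule —
ultralow = minimum observed vote count v, low = {v, v+1} — covers transferred
cohorts where no patient reaches 0 votes.

COX-RS fits one univariate proportional-hazards coefficient per selected
miRNA on standardized training expression and scores each patient by
RS = Σⱼ β̂ⱼ zⱼ. A probability of exactly 0.5 votes 1 (toward recurrence),
the conservative direction for a classifier meant to justify *withholding*
therapy.

## Cross-validation and the leakage ban

Evaluation uses leave-one-pair-out cross-validation (LOPO-CV): each fold
holds out one matched pair and repeats the **entire** pipeline — paired
differential expression, FDR feature selection, model fitting — on the
remaining pairs only. Selecting features once on the full data and
cross-validating afterwards is the classical selection-bias leak in small
expression studies; the package structurally prevents it, and the
null-calibration acceptance test verifies that with no planted signal every
method's held-out accuracy stays within [0.4, 0.6].

Per fold: a two-sided paired t-test per miRNA on case-minus-control
differences (df = n−1), Benjamini–Hochberg step-up adjustment, selection at
q < 0.05. If nothing clears the threshold the fold falls back to the top-10
smallest-p features so cross-validation never aborts; the feature set records
which mode produced it. Features with zero training variance are dropped with
a logged warning; zero-variance *differences* get p = 1 and a flag rather
than an error.

## External-cohort transfer

Cohorts profiled on other platforms are harmonized by feature-ID
intersection (kept in reference order). Because per-fold FDR selection
rarely survives a sparse platform overlap, per-method feature sets are
*preselected* on the reference cohort: shared features are ranked by the
reference paired-DE p-value and each top-k set (k ∈ {5, 10, 20, 50}) is
scored by the method's reference LOPO-CV accuracy; the best k wins, smaller
k on ties. Validation inside the external cohort then cross-validates with
those fixed sets. Paired external cohorts use LOPO folds; unpaired ones use
seeded one-case-plus-one-control folds, with leftover samples of the larger
class in singleton folds so every sample is voted exactly once.

## Evaluation statistics

- **Confusion metrics** per method, with a one-sided exact binomial test of
  accuracy against chance (0.5).
- **Fisher's exact test**, one-tailed: enrichment of recurrence-free
  patients in a risk group with all 2×2 margins fixed (upper hypergeometric
  tail). This direction matches the intended clinical claim — that the
  ultralow group is safe to spare therapy.
- **Kaplan–Meier curves** per risk group (product-limit estimates at event
  times, with at-risk counts).
- **Cox hazard ratio** for high-vs-rest with Wald 95% CI and p. When all
  events fall in one group the partial likelihood is monotone and no finite
  HR exists; the result is flagged rather than reported as a number.
- **Logistic independence**: one multivariable logistic regression of risk
  group membership on ER status (pos = 1), age (> 50), tumor size (≥ 20 mm),
  grade (≥ 2) and outcome. A covariate that perfectly separates membership
  (e.g. outcome for an ultralow group containing no recurrences) is excluded
  from the fit and reported `n/a` instead of crashing the fit. The coding is
  configurable.

## Synthetic cohort generator

Real patient-level data cannot ship with the package, so all tests and
examples run on simulated cohorts from `simulate_cohort`.

Construction, with δ = `effect_size`:

1. Each sample gets a latent risk score: cases ~ N(+δ/2, `latent_sd`²),
   controls ~ N(−δ/2, `latent_sd`²). An `indolent_fraction` of controls is
   shifted further down by `indolence_shift`·δ, giving controls the graded
   structure that spreads vote counts over 0–7 instead of a clean binary
   split. Every shift scales with δ, so δ = 0 yields a fully exchangeable
   null — the property the leakage tests rely on.
2. `n_informative` randomly chosen miRNAs equal latent score plus noise;
   the rest are pure noise. Noise is unit-SD and equicorrelated at
   `feature_correlation` via a shared per-sample factor. The overall planted
   case-minus-control mean difference is therefore
   δ·(1 + `indolent_fraction`·`indolence_shift`).
3. Case event times are log-normal (mean `case_time_mean` months, shape
   `case_time_sigma`), resampled to stay within the 120-month case horizon;
   control follow-up is normal (`control_followup_mean`,
   `control_followup_sd`), truncated below at `control_followup_min`.
4. Pair covariates (age, size, ER/PR, grade, type, surgery year) are drawn
   once per pair and shared by both members, mimicking exact matching.

### Parameter defaults and rationale

| Parameter | Default | Why |
|---|---|---|
| `n_pairs` | 80 | reference cohort size (80 matched pairs) |
| `n_features` | 1212 | mature-miRNA panel size |
| `n_informative` | 50 | small planted panel; enough for FDR selection to find |
| `effect_size` | 1.0 | ~1 noise-SD shift; moderate, neither trivial nor hopeless |
| `indolent_fraction` | 0.5 | half the controls "very indolent"; spreads votes |
| `indolence_shift` | 1.0 | indolent controls one extra δ below the rest |
| `feature_correlation` | 0.2 | miRNAs co-regulate; independence would be unrealistically easy |
| `latent_sd` | 0.5 | within-group heterogeneity below the group separation |
| `case_time_mean` | 58.5 | months; matches the cohort's mean time to metastasis |
| `case_time_sigma` | 0.55 | right-skewed event times within the 120-month horizon |
| `control_followup_mean` | 250.35 | months; matches the cohort's mean control follow-up |
| `control_followup_sd` / `min` | 30 / 60 | long censored follow-up, never below 5 years |

### Scope and limits of the simulator

The generator is a *test harness*, not a biological model. It plants a
single one-dimensional latent signal; real recurrence biology is
multi-pathway. Noise is equicorrelated rather than block-structured;
expression is Gaussian on the log scale with no platform, batch, or
missing-value artifacts; covariates are drawn independently of the planted
signal, so the simulated classifier is independent of clinical markers *by
construction* (the independence test on simulated data checks machinery, not
biology). Conclusions about real cohorts require real cohorts.

## Numerical choices

- **Paired t-test / BH**: vectorized closed forms; BH is the step-up
  `q(i) = min_{j≥i} p(j)·m/j`, clipped at 1, mapped back to input order.
  Both are cross-checked against independent implementations in the tests
  at 1e-12 relative tolerance.
- **Univariate Cox fits** (COX-RS trains one fit per selected miRNA per
  fold, thousands per run) use a vectorized Newton solver on the Breslow
  partial likelihood: all features share the sorted risk-set prefix sums, so
  score and information are scalar per feature and vectorize across the
  feature axis. A ridge term (1e-6) and a coefficient bound (|β| ≤ 20) keep
  estimates finite under monotone likelihood; steps are clipped at ±2 and
  the per-sample linear predictor is max-shifted before exponentiation for
  overflow safety. Reference Cox fits (the hazard-ratio evaluation, KM
  curves) use `lifelines`, which also serves as the independent oracle for
  the Newton solver in the test suite. Breslow and Efron tie-handling differ
  only on tied event times; the oracle comparison uses tie-free data.
- **Platt scaling** for the SVMs uses sigmoid calibration on 5-fold
  cross-validated decision values (deterministic, unshuffled folds).
- **Standardization** constants (mean, SD) are always estimated on the
  training fold only and stored in the fitted model.
- All randomness flows from explicit integer seeds; per-fold seeds are
  derived as `(seed + 10007·(fold+1)) mod 2³¹`, so runs are exactly
  reproducible and folds are decorrelated.

## Limitations

- Accuracy significance uses a one-sided exact binomial test against 0.5;
  LOPO-CV folds are not strictly independent, so this p-value is an
  approximation and should be read qualitatively.
- The `auto` cutoff depends on the observed vote minimum and is therefore
  dataset-dependent; comparisons of ultralow groups across cohorts with
  different cutoffs are qualitative.
- The unpaired external-cohort fold scheme is a pragmatic stand-in for a
  design the matched-pair pipeline was not built for; singleton folds make
  each sample's training set differ slightly in class balance.
- No batch correction, normalization, or platform harmonization beyond
  feature-ID intersection is provided; inputs are assumed pre-normalized,
  log-scale expression.
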