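# Methods

## The simulated study

The package models a pragmatic trial of a self-managed digital lifestyle
tool in type 2 diabetes with two control conditions: a randomized 12-week
wait-list phase, and an extended open-label phase in which all participants
have access to the tool and are compared with matched usual-care controls
drawn from a registry pool. The generator is not a fit to any patient-level
data set; it encodes the study's design parameters and published marginal
characteristics as ground truth so that every estimator in the package can
be validated by parameter recovery.

### Outcome model

For participant *i* at visit day *t*:

    HbA1c_i(t) = b_i + d·t/365.25 + e_i·r_i(t) + ε_it

* `b_i` — baseline HbA1c, truncated normal with floor 52 mmol/mol. The
  configured mean (63.2) and SD (10.2) describe the *enrolled* population,
  so the pre-truncation location is solved (Brent root-find on the
  truncated-normal mean) such that the post-truncation mean equals the
  configured value.
* `d` — secular usual-care drift. Stated in NGSP %/year (default 0.15) and
  converted to IFCC units by the slope of the master equation,
  10.929 mmol/mol per NGSP %, i.e. 1.639 mmol/mol/year. The drift applies
  to participants and registry patients alike, so it cancels from
  user-vs-control contrasts.
* `e_i` — usage effect. Class effects are **marginal means**: −6.5
  (biweekly), −4.2 (monthly), −3.6 (bimonthly), 0 (non-user) mmol/mol at
  full ramp. The MOD subgroup deviation enters mean-centered,
  `e_i = class + mod_extra·(mod_i − 0.30)` for active classes, so the
  marginal class contrast equals the configured class effect exactly and
  the MOD-vs-non-MOD contrast equals `mod_extra` (−2.8) — both are then
  clean recovery targets.
* `r_i(t)` — linear ramp from 0 to 1 over 365 days, starting at day 0 for
  the tool arm and at the second visit (~day 91) for the wait arm, flat
  afterwards. The ramp gives the randomization phase a small early
  contrast and the open-label phase the full one, qualitatively matching a
  behavioural intervention that needs time to act.
* `ε_it` — i.i.d. N(0, 4) mmol/mol visit noise (zero at the baseline
  visit, which defines baseline). An SD of 4 per visit implies an SD of
  ~5.7 for a change between two visits, consistent with the design
  assumption of 6 for the change over 12 weeks.

Visits follow the trial schedule: days 0, 91, 182, 273, 365, then
semiannual, with ±7-day jitter. Dropouts (14% tool arm, 4% wait arm)
contribute only their baseline visit. Medication changes arrive as a
Poisson process (0.2/year); analyses truncate each series at the first
change, mirroring a last-visit-with-unchanged-medication rule.

### Covariates, confounding and the MOD flag

Age, BMI and sex are drawn from the configured marginals. Usage class is
assigned by a multinomial logit around the configured shares (0.215 /
0.314 / 0.215 / 0.256) with a mild adherence gradient (+0.3 logit per SD
of age, −0.06 per SD of BMI toward more frequent use). This is the
confounding structure the propensity machinery must remove. The MOD flag
marks the top 30% of a noisy BMI ranking — correlated with BMI, hitting
the configured fraction exactly.

Secondary biomarkers (HOMA2 indices, fasting glucose, lipids, blood
pressure) are emitted directly as baseline-plus-scaled-effect-plus-noise
series; the HOMA2 values are generator outputs, not computed from glucose
and C-peptide. Weight loss under treatment feeds the bioimpedance
channel: each person's fat-free mass is held fixed while weight declines,
so fat percentage falls mechanically. Raw resistance values are obtained
by inverting the fat-free-mass equation from a target FFM fraction
(N(0.65, 0.06) of weight for males, N(0.55, 0.06) for females, reactance
N(50, 8) ohm), which guarantees FM ≥ 0 and makes the measurement module's
round-trip exact.

### Theme completions

Completions per inter-visit period are negative binomial (dispersion 8)
with per-quarter means 6.5 / 3 / 1.5 / 0 by usage class, scaled by period
length; wait-arm participants complete nothing before the merge. The
distribution of completions per quarter is not identified by any published
quantity beyond coarse bin counts, so these means are a loose calibration
(biweekly ≈ one theme per two weeks), not a fit.

## Analysis components

* **Trajectory classifier.** Rules applied in fixed order 1→4, first match
  wins: sustained decrease (≥1 strictly below baseline, all ≤); sustained
  increase (mirror); oscillatory decreasing (majority, read as strictly
  more than half, ≤ baseline, but not all); oscillatory increasing (half
  or more strictly above, but not all). A series whose follow-ups all
  equal baseline is reported as unclassifiable rather than forced into a
  category. With this order the labels are exhaustive and mutually
  exclusive for every series containing at least one non-tie
  (property-tested).
* **BCT scoring.** Responder means strictly lower HbA1c over the period;
  a zero change is "similar", hence non-responder. Dominance weights are
  normalized to sum to one per theme (user-supplied weight tables
  override). Each completion event counts by default; `count_repeats=False`
  counts a participant at most once per theme per quarter. The chi-square
  treats weighted scores as counts; because the statistic then scales
  linearly with the overall weight normalization, the function warns
  whenever scores are non-integer.
* **Matching.** Greedy nearest-neighbour without replacement in random
  order under a fixed seed, within exact sex strata, Mahalanobis metric
  from the covariance of the full candidate pool. Index dates are chosen
  uniformly at random among admissible registrations (≥ 2 years after
  diagnosis, ≥ 1 year of subsequent data, no medication change in the
  follow-up window). Calipers and matching with replacement are not
  implemented.
* **Propensity scores.** Gradient boosting with shrinkage 0.001 and
  interaction depth 3 (histogram-based trees, which split only on observed
  values, so missing features need no imputation). The tree count is
  selected on a grid by K-fold cross-validation minimizing the mean
  absolute SMD of the features under the implied inverse-probability
  weights — balance, not likelihood, is the selection criterion.
  Probabilities are clipped to (1e-6, 1−1e-6) before inversion.
* **Weight schemes.** Dropout and adherence adjustments weight the
  treatment/access group by 1/p and fix the wait group at exactly 1;
  the user-vs-non-user scheme weights by 1/p and 1/(1−p). Weighted
  contrasts use WLS with the HC1 sandwich variance (the variant is a
  package choice; "robust sandwich" alone does not pin one down, and HC1's
  small-sample correction is the standard default at these sizes).
* **Contrasts.** Welch (unequal-variance) t-tests wherever an independent
  t-test is called for; the difference is negligible at these group sizes
  and the robustness is free. No multiplicity adjustment anywhere; all
  p-values are raw and labelled as such.
* **Mediation.** Linear no-interaction decomposition: a-path
  mediator ~ exposure (+ mean-centered moderators), outcome model
  outcome ~ exposure + mediator (+ moderators); indirect = a·b,
  total = direct + indirect, which equals the exposure coefficient of the
  reduced outcome model to numerical precision (asserted at 1e-9).
  Percentile bootstrap (default 5000 draws) resamples whole subjects.
* **Design.** Normal-approximation sample size
  n₁ = ⌈(1 + 1/k)(z₁₋α/₂ + z_pow)² σ²/δ²⌉, n₂ = k·n₁ — chosen over the
  iterative t-based version because it reproduces both of the study's
  printed allocations exactly (142 + 142, and 24 + 48). The Monte-Carlo
  companion simulates the stated alternative and reports the t-test
  rejection rate.

## Problem sizes and defaults

The default generator scale is 370 participants and 10,000 registry
patients; full generation takes well under a minute and the complete
pipeline (including a 10,000-replicate power simulation and a 1,000-draw
mediation bootstrap in the orchestrated run) a few minutes on one CPU.
The parameter-recovery test averages 200 seeded replicates of the
biweekly-vs-non-user weighted contrast at the default cohort size with
medication changes disabled (so every series reaches full follow-up and
the estimand is exactly the configured −6.5). Tests use smaller cohorts
(60–200 participants) where only structural properties are at stake.

## What passing tests do and do not show

The generator produces Gaussian noise, linear drift, a deterministic ramp
and independent visits. Real HbA1c series have autocorrelated
within-person variation, assay batch effects, seasonal structure,
informative missingness and treatment effects that interact with baseline
in ways no four-class model captures. Recovery of the configured effects
therefore validates the estimators and their wiring — not the clinical
magnitudes, which in the source setting depend on unavailable patient
data. The trajectory-pattern proportions of a real registry are likewise
not a target: the classifier and its comparison machinery are what is
verified.

## Known limitations

* The oscillatory pattern definitions overlap at the boundary as stated;
  the fixed rule order resolves ties deterministically but other readings
  ("majority" as ≥ half; baseline-ties counting toward "above") would
  shift borderline series between categories 3 and 4.
* Chi-square on weighted scores is not scale-invariant (warned at run
  time); with normalized per-theme weights the total score equals the
  total completion count, which bounds the distortion.
* Greedy matching is order-dependent; optimal (global) matching is not
  implemented.
* The cross-validated balance criterion for the tree count is evaluated
  on out-of-fold probabilities but the final model is refit on all data
  at the selected count, so the reported balance is mildly optimistic.
* EQ-5D scoring, HOMA2 computation and the long-horizon health-economic
  cohort model are out of scope; their inputs/outputs appear only as
  pass-through quantities (the fixed per-user cost components).
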