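# glycotrial

Simulation and analysis toolkit for trials of self-managed digital lifestyle
treatment in type 2 diabetes. It is written for biostatisticians and trial
methodologists who want to exercise — and stress-test — the full analysis
chain of such a study without access to patient data: a synthetic cohort
generator with known ground truth stands in for the trial and its registry
control pool, and every downstream method runs on it unchanged.

## What it implements

**Synthetic cohort.** A randomized wait-list trial (default 370 participants,
61.9% male, age 63.3 ± 9.7 y, BMI 31.1 ± 5.2, baseline HbA1c 63.2 ± 10.2
mmol/mol with an enrollment floor of 52) with quarterly visits in year one
and semiannual visits after, differential dropout (14% vs 4%), four usage
classes (biweekly / monthly / bimonthly / non-user), a 30% MOD subgroup
(obese, insulin-resistant) with an amplified response, a usual-care registry
pool under a secular HbA1c drift of 0.15 NGSP %/year (= 10.929 × 0.15 ≈ 1.64
mmol/mol/year), and an 80-theme catalog over 24 behavior change techniques
(BCTs) with per-theme dominance weights.

**Measurements.** Sex-specific single-frequency bioimpedance equations for
fat-free mass, FFM = −4.104 + 0.518 h²/R + 0.231 w + 0.130 Xc (+ 4.229 for
males), total body water, fat mass FM = w − FFM, muscle mass MM = 0.64 FFM;
IPAQ MET-minutes (8.0/4.0/3.3 MET) and the kcal conversion
MET-min × (w / 60 kg); per-user tool cost aggregation.

**Trajectories.** Four-pattern HbA1c progression classifier (sustained
decrease / sustained increase / oscillatory decreasing / oscillatory
increasing) over a three-year frame with eligibility filters (baseline ≥ 52
mmol/mol, ≥ 3 measurements, no medication change), and Fisher's exact test
for sustained-improvement rates between groups.

**Exposure and BCTs.** Quarterly exposure–response bins {0, 1–4, ≥5 themes}
with mean HbA1c change ± SEM, and weighted responder / non-responder scores
per BCT with a Pearson chi-square comparison.

**Inference.** Exact-sex + Mahalanobis nearest-neighbour 1:2 matching of
registry controls with random index dates (≥ 2 years post-diagnosis) and SMD
balance reporting; gradient-boosted propensity scores (shrinkage 0.001,
depth 3, tree count selected by cross-validated balance) feeding three
inverse-probability weight schemes; weighted least-squares contrasts with
HC1 sandwich errors; Welch t endpoint contrasts; MOD × group interaction;
linear mediation decomposition (indirect = a·b, total = direct + indirect)
with percentile bootstrap CIs; and the normal-approximation sample-size
formula n = (1 + 1/k)(z₁₋α/₂ + z_power)² σ²/δ² with a Monte-Carlo power
companion.

## Worked example

```
$ python examples/matching_and_weighting.py
covariate balance (standardized mean difference):
covariate   smd_pre  smd_post
      age -0.254656 -0.004637
      bmi  0.109039 -0.001498
    hba1c -0.537388 -0.037737
weighted HbA1c contrast -6.22 mmol/mol (95% CI -8.14 to -4.29), 300 trees
```

Matching shrinks every covariate imbalance to near zero, and the
inverse-probability-weighted contrast between biweekly users and non-users
estimates −6.22 mmol/mol against the generator's true effect of −6.5 —
within the simulation's sampling error. The other scripts in `examples/`
each demonstrate one capability (cohort simulation, body composition,
trajectory patterns, exposure/BCT scoring, mediation and power, and the full
pipeline, which also renders the baseline table, the 13-endpoint contrast
table and the exposure-bin table as CSV).

A thin CLI mirrors the pipeline stages
(`glycotrial simulate|measure|patterns|exposure|bct|match|weights|contrast|mediate|power|all`),
each with `--config`, `--seed` and `--out`.

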