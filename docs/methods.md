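# Methods

## Cohort model

The unit of analysis is the hip. A record carries demographics (age, sex,
BMI), etiology (idiopathic / glucocorticoid / alcohol), the three imaging
factors (ARCO stage I/II, JIC type A/B/C1/C2, necrotic-area fraction or
category), and the follow-up outcome: a collapse indicator and a time in
years, administratively censored at 5 years. Bilateral hips share a
`patient_id` (at most two records); within-patient correlation is ignored
throughout, matching the source analysis — all inference treats the 202
hips as independent. Only pre-collapse stages occur by construction
(collapse defines ARCO III+), so the enumerations are deliberately
restricted.

Necrotic area may be recorded as a fraction, a category, or both. The
discretization is `[0, 0.30) → <30 %`, `[0.30, 0.50] → 30–50 %`,
`(0.50, 1] → >50 %`: the published bins are "<30 %", "30–50 %" and
">50 %", so a boundary value of exactly 50 % belongs to the lower stratum
and scores 1 point. Whether "area" is a planar CT fraction or a volume
fraction is not specified upstream; the scorer is agnostic.

## The matrix score

Each factor contributes 1 or 2 points (ARCO II, lateral-column JIC, area
> 50 % are the 2-point levels) and the composite score is their product,
taking exactly the values {1, 2, 4, 8}. The product form means the score
is monotone in every component and compounds risk multiplicatively; the
value 3 is not attainable, which matters for how the ROC cut-off is
reported (below).

## The reconstructed cohort

The published grouped tables determine, per score stratum (sizes
25/62/85/30), the cumulative collapse counts at years 1/3/5:
1/15/31/12, then 1/18/46/19, then 1/20/50/27 (98 collapses of 202 hips).
The fixture places each event at the right endpoint of the interval in
which it is known to have occurred — the tables report only cumulative
counts at those horizons — and censors the remaining 104 hips at 5 years.
Lost-to-follow-up patients were excluded upstream, so administrative
censoring at 5 years is the only censoring mechanism assumed.

Two consequences are worth stating plainly. First, with events only at
1/3/5 and censoring only at 5, the product-limit estimator equals the
empirical survival fraction at each horizon, so the reconstructed KM curve
reproduces the printed 70.8 / 58.4 / 51.5 % exactly. Second, each record
carries a *representative* ARCO/JIC/area combination whose point-product
equals its stratum score (the joint factor distribution was never
published), and no age/sex/BMI/etiology; the fixture is faithful to the
score strata and outcome timings only, and the covariate sections of the
report skip gracefully on it.

One printed inconsistency is resolved in favour of arithmetic: the
univariate table's area-row totals (77 and 34) disagree with their own
cell sums (40+39 = 79, 28+4 = 32); the cells are taken as authoritative
because they reconcile with the collapse/non-collapse margins (98/104).

## Association statistics

* **Chi-square** — uncorrected Pearson statistic, df = (r−1)(c−1), upper
  tail p. No continuity correction anywhere: the printed 2×4 statistics
  (12.295 / 29.897 / 50.680) and the sex p-value (0.426) are uncorrected
  values; a Yates-corrected 2×2 would not reproduce them. Tables with a
  zero margin are rejected (an expected count of zero).
* **t-test** — pooled-variance Student's t from group summaries
  (mean, SD, n), df = n₁+n₂−2, two-sided. Pooled rather than Welch: the
  pooled form reproduces the printed p = 0.006 (age) and 0.725 (BMI).
* **Logistic regression** — maximum likelihood (statsmodels `Logit`,
  Newton iterations, convergence tolerance 1e−10, at most 50 iterations)
  with dummy coding against explicit reference levels (stage I, type A,
  area <30 %, score 1). Wald statistic (B/SE)², OR = exp(B),
  CI = exp(B ± 1.96·SE). Non-convergence and (quasi-)separation raise an
  explicit `SeparationError` instead of returning unbounded coefficients.
  No multiple-testing adjustment is applied, matching the source.

Because the matrix score is a deterministic function of the three factors,
a single joint model containing both is rank-deficient. The pipeline
therefore fits **two** models — a components model (age, ARCO, JIC, area)
and a score model (age, score) — and claims neither to equal the published
adjusted ORs, whose individual-level inputs were never released. On
202-hip cohorts the score-1 stratum has a 4 % collapse rate, so a
realistic draw has a ~36 % chance of zero events in the reference stratum;
the resulting quasi-separation is reported as a structured diagnostic in
the score model rather than as inflated coefficients. The logistic
machinery is validated instead by parameter recovery: over 200 seeded
replicates of n = 2000 the per-coefficient bias is below 0.1 and the
pooled 95 % Wald coverage falls in [0.93, 0.97].

## Survival analysis

Kaplan–Meier estimation and the k-group log-rank test are delegated to
lifelines behind the package surface; censoring at an event time is
processed after the events at that time (the standard convention), and
recorded times are treated as exact even though real collapse times are
interval-known from imaging visits — an approximation the fixture's
endpoint placement makes exact at the reported horizons. The median is the
smallest t with S(t) ≤ 0.5; its CI inverts the pointwise Greenwood band
(Brookmeyer–Crowley), the source's method being unnamed.

On the reconstructed cohort the 5-year survival is 51.5 % > 50 %, so the
product-limit median is **not reached**. The upstream report of a 3-year
median (95 % CI 3.176–3.672) is arithmetically incompatible with its own
survival curve (it may be a restricted mean); the package reports the
standard estimator and flags the discrepancy rather than matching the
3-year figure. Likewise the printed log-rank χ² = 45.725 depends on
unpublished event timings; the endpoint-placed fixture yields 45.10 with
p < 10⁻⁹, and the test's calibration is checked by simulation: under
identical hazards in all strata the rejection rate at α = 0.05 over 500
seeded 202-hip replicates is 0.050.

## Grouped ROC

For a 4-level ordinal score the ROC is fully determined by per-level
collapse/non-collapse counts: one operating point per threshold between
adjacent levels ("positive" = score strictly above threshold) plus the
(0,0)/(1,1) anchors. The trapezoidal area under this polygon is
algebraically the tie-corrected rank probability
P(S_pos > S_neg) + ½P(tie), an identity the tests verify by brute-force
pair expansion; individual-level and grouped computation coincide for a
score with only four values. The Youden cut-off maximizes
J = sensitivity + specificity − 1 over interior points, ties broken toward
higher specificity, and is reported as the midpoint of the bracketing
score levels — hence the cut-off "3" between attainable scores 2 and 4.
The AUC standard error is Hanley–McNeil
(Q₁ = A/(2−A), Q₂ = 2A²/(1+A)); on the study counts it gives a 95 % CI of
(0.705, 0.836), within ~0.002 per bound of the published (0.707, 0.834)
whose method was unnamed — documented, not chased. Degenerate AUCs of 0 or
1 get a zero-width interval.

## Synthetic-cohort generator

`CohortConfig` defaults *are* the published study conditions: 202 hips;
score probabilities 25/202, 62/202, 85/202, 30/202; per-score conditional
collapse probabilities over the intervals (0,1], (1,3], (3,5] derived from
the cumulative tables (e.g. score 8: 12/30, 7/18, 8/11, compounding to
90 % at 5 years); outcome-conditional age (52.48 ± 12.18 collapsed,
47.60 ± 12.57 not) and BMI normals, truncated to plausible clinical
ranges; sex/etiology marginals from the demographic table. Collapse is a
sequential Bernoulli walk over the three intervals; event times sit at the
interval endpoint (`endpoint` mode, which reproduces the fixture's
structure) or uniformly within the interval (`uniform`, the default, for
realistic-looking curves). Factor combinations are drawn uniformly over
the point patterns whose product equals the assigned score, with levels
inside a point class weighted by the published margins — the true joint
distribution of ARCO × JIC × area was never printed, so only the score
distribution and the marginals are emulated. Not emulated at all:
bilateral correlation, early dropout, interval-censored observation, and
any covariate–factor dependence beyond outcome-conditional age/BMI.
Passing tests on these cohorts therefore validate the estimators under
the stated generative model, not robustness to those real-data features.

Every stochastic entry point takes an explicit seed (default 20161001);
identical seeds give byte-identical cohorts.

## Problem sizes and numerical choices

The validation studies use 200 replicates of n = 2000 for logistic
recovery, 500 replicates of n = 202 for log-rank type-I error, and a
single n = 50 000 cohort for end-to-end KM calibration (agreement within
±0.01 of the configured mixture survival) — sizes at which Monte-Carlo
error is comfortably inside the asserted bands while the full suite runs
in well under a minute per study. Ties in the Youden search are broken
toward specificity; chi-square tables with a zero margin, cohorts with no
events, and all-one-class ROC inputs raise structured errors rather than
NaNs; logistic designs are checked for full rank before fitting.
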