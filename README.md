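# nonfh-collapse

Natural-history analysis of femoral-head collapse in non-traumatic
osteonecrosis of the femoral head (NONFH), organised around a composite
**matrix score** for pre-collapse hips.

## The problem and the model

Collapse of the necrotic femoral head is the decisive event in NONFH: once
the articular surface fails, hip function deteriorates and arthroplasty
usually follows. Three classical imaging factors each predict collapse only
weakly on their own:

* **ARCO stage** — I (MRI-only changes) scores 1 point, II (radiographic
  changes without collapse) scores 2;
* **JIC lesion location** — medial-column types A/B score 1, lateral-column
  types C1/C2 score 2;
* **necrotic area** — ≤ 50 % of the femoral head scores 1, > 50 % scores 2.

The matrix score is the **product** of the three points,

```
S = s_ARCO × s_JIC × s_area ∈ {1, 2, 4, 8},
```

so one high-risk factor doubles the score and the three together compound
multiplicatively. The package implements the score and the full analysis
pipeline built around it for a hip-level cohort followed 5 years:

* contingency tables with uncorrected Pearson χ², pooled-variance t-tests
  from group summaries, and reference-coded multivariate logistic
  regression with Wald odds ratios (`nonfh_collapse.stats`);
* Kaplan–Meier product-limit curves with Greenwood standard errors,
  Brookmeyer–Crowley median CIs, and the k-group log-rank test
  (`nonfh_collapse.survival`);
* grouped ROC analysis of the ordinal score — operating points per
  threshold, trapezoidal AUC with Hanley–McNeil CI, Youden-optimal
  cut-off (`nonfh_collapse.roc`);
* a deterministic 202-hip cohort reconstructed from the published grouped
  tables (`nonfh_collapse.cohort.reconstructed_fixture`), and a seeded
  synthetic-cohort generator with score-stratified discrete-time collapse
  hazards (`nonfh_collapse.synthetic`) for parameter-recovery and
  calibration studies.

## Worked example

```python
import nonfh_collapse as nc

cohort = nc.reconstructed_fixture()          # 202 hips, 98 collapses
report = nc.run_full_analysis(cohort).to_dict()

print(report["cohort"]["collapse_rate"])     # 0.4851... (48.5 %)
print(report["collapse_by_horizon"]["year_5"]["chi_square"])  # 50.680...
roc = report["roc"]
print(roc["auc"], roc["cutoff"])             # 0.7707..., 3.0
surv = report["survival"]["overall"]["survival_at_years"]
print(surv)                                  # {'1': 0.7079, '3': 0.5842, '5': 0.5149}
```

Running the numbered drivers reproduces the same analysis as a narrative,
writing tables under `results/`:

```text
$ python analysis/03_survival_and_roc.py
overall survival at 1/3/5 years: 70.8%/58.4%/51.5%
product-limit median: not reached (5-year survival exceeds 50%)
log-rank across scores: chi2 = 45.099, df = 3, p = 8.81e-10
grouped ROC: AUC = 0.771 (95% CI 0.705-0.836); Youden cut-off = 3 (sens 0.786, spec 0.635)
```

Reading: per-score 5-year collapse rates rise monotonically
(4.0 % → 32.3 % → 58.8 % → 90.0 %), the score separates the survival
curves decisively, and the ROC cut-off of 3 (midpoint between attainable
scores 2 and 4) classifies hips scoring 4 or 8 as high risk with
sensitivity 0.786 and specificity 0.635.

A CLI mirrors the library: `collapse-matrix score|stats|km|roc|simulate|report`
with `--in cohort.csv` or `--fixture`, e.g.

```bash
collapse-matrix simulate --n 500 --seed 7 --out cohort.csv
collapse-matrix report --in cohort.csv --out report.json
```

## Data

No individual-level dataset is distributed; the reconstructed cohort is
derived entirely from published grouped counts, and the synthetic
generator produces arbitrary cohorts with the same grouped structure (see
`docs/methods.md` for what it does and does not emulate).
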