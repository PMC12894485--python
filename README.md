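# mscsf

Validation machinery for **CSF-proteomic molecular tests in multiple
sclerosis**, built as a reusable Python library: a diagnostic classifier
(MS vs non-MS), a disease-staging classifier (relapsing–remitting vs
progressive MS), and a prognostic chain that converts a CSF-predicted
severity score into a predicted future disability level — together with a
seeded synthetic-cohort generator so every stage is testable without any
patient data.

## Who this is for

Biostatisticians and translational researchers who need to (re)run an
external-validation analysis of panel-based proteomic classifiers:
simulate multicenter cohorts with known ground truth, engineer the
age/sex-adjusted log-ratio features such classifiers consume, train and
apply probability-producing random forests under strict external-validation
discipline, and quantify performance with first-principles ROC inference.

## The models at the core

- **Features.** For each sample, protein abundances (relative fluorescence
  units, RFU) are log-transformed and residualized against a healthy
  reference (per-protein OLS of log RFU on age and sex). A panel of ratios
  turns these into features: `x_{A/B} = adj(A) − adj(B)`. Log-ratios are
  invariant to per-sample rescaling of all RFUs. The packaged diagnostic
  panel has 20 ratios over 21 proteins; the staging panel 21 ratios over 24
  proteins; the severity panel 57 ratios over 75 proteins.
- **Classifiers.** Random forests emit probabilities in [0, 1] (vote
  fractions over the trees), dichotomized at a predefined cutoff of 0.5
  (ties assigned negative). A regression forest predicts the composite
  severity score MS-DSS from severity-panel ratios.
- **ROC inference.** AUROC is the Mann–Whitney statistic
  `P(score⁺ > score⁻) + ½·P(tie)`; confidence intervals come from a
  stratified percentile bootstrap; significance against AUC = 0.5 from the
  Mason–Graham test (exact Mann–Whitney enumeration at small n,
  tie-corrected, continuity-corrected normal approximation otherwise);
  paired classifier comparisons from DeLong's placement-value test.
- **Prognosis.** With `m` the CSF-predicted severity,
  `slope_cw = a + b·m` (CombiWISE units/year, fitted line),
  `Δcw = slope_cw · interval`, and a fitted monotone quadratic
  `EDSS = q(cw)` maps between scales:
  `EDSS_followup = clamp(EDSS_base + q(q⁻¹(EDSS_base) + Δcw) − EDSS_base, 0, 10)`.
  Intermediate arithmetic uses the continuous CombiWISE scale (0–100)
  because per-interval changes are usually below the 0.5-point EDSS grid.
- **Simulator.** Disease effects enter through scalar latent scores
  `u ~ N(effect·1[class], 1)` loaded onto panel proteins with alternating
  signs, so the Bayes AUROC of each task is exactly `Φ(effect/√2)` — set
  `effect = effect_for_auc(target)` to calibrate. Defaults are calibrated
  to AUROC 0.94 (diagnosis) and 0.76 (staging) at the validation-cohort
  composition 65/31/30/34.

## Worked example

```python
from mscsf.pipeline import PipelineConfig, run_full_validation

report = run_full_validation(PipelineConfig(seed=7))
diag = report["diagnostic"]["pooled"]
print(diag["auc"], diag["ci_lower"], diag["ci_upper"])
```

Running `python examples/05_full_validation.py` prints (seed 7):

```
diagnostic AUROC 0.920 (95% CI 0.875-0.957, p 7.39e-20)
  center 1: AUROC 0.918 (16 MS / 16 non-MS)
  center 2: AUROC 0.911 (30 MS / 12 non-MS)
  center 3: AUROC 0.915 (50 MS / 36 non-MS)
cutoff 0.5: sens 0.85 spec 0.84 acc 0.85
staging AUROC 0.697 (p 9.45e-04)
prognosis (clinician baseline, n=84): rho 0.53, R^2 25% -> 37%
misclassified MS: 14 of 96
```

Reading: the diagnostic classifier separates the 96 simulated MS
participants from the 64 controls with AUROC 0.92 on this draw (the
25-seed mean sits at the calibrated 0.94); staging is harder (0.70 here,
0.76 on average); and adding the CSF-predicted disability change to
baseline EDSS raises the explained variance in follow-up EDSS from 25% to
37% in the 84 participants with complete timelines. Each `examples/`
script demonstrates one capability and states what its numbers mean.

A thin CLI wraps the pipeline: `mscsf simulate --seed 1 --out cohort/`,
`mscsf run-all --seed 1 --out results/`, `mscsf audit --report
results/report.json`. A per-participant results table (identifier,
diagnosis, model probabilities, optional EDSS columns) can be analyzed
directly with `mscsf run-all --supplementary results.csv --out out/`.

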