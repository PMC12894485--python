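# Methods

This note documents the generative model behind the synthetic cohorts,
the statistical procedures in each stage, the defaults and why they were
chosen, and what the package's tests do and do not establish about real
data.

## The validation problem

Panel-based CSF proteomic classifiers for multiple sclerosis output an MS
probability, a progressive-MS probability, and a predicted composite
severity score (MS-DSS). External validation asks three questions on a
cohort disjoint from training: does the MS probability separate MS from
inflammatory/non-inflammatory mimics (AUROC, confusion metrics at the
predefined 0.5 cutoff, comparison with oligoclonal bands and the IgG
index)? Does the progMS probability separate relapsing–remitting from
progressive disease, and does it carry prognostic information beyond age
and baseline disability? And can the predicted severity score, pushed
through cross-scale conversion models, predict the EDSS actually measured
years later?

## Synthetic cohort generator

### Signal model

A uniform abundance shift on every panel protein would cancel exactly in
log-ratio features, so disease signal enters through scalar latent
scores:

- diagnostic score `u_d ~ N(diag_effect · 1[MS], 1)`;
- staging score `u_p = prog_effect · 1[progMS] + 0.5·(severity residual)
  + √(1−0.25)·ε`, whose class-conditional distribution is `N(shift, 1)`;
- latent severity `s ~ N(1[progMS], 1)`.

Each score is loaded onto its panel's proteins with alternating signs
(±0.5 per log-RFU), so chained ratios carry `±u` plus residual noise
(`noise_sd = 0.15` per protein, i.e. √2·0.15 per ratio). Because all
class information flows through a scalar with two-unit-variance-normal
geometry, the Bayes AUROC of each task is exactly `Φ(effect/√2)`
(`analytic_auc`), and `effect_for_auc(target)` calibrates the generator:
defaults `diag_effect = effect_for_auc(0.94) ≈ 2.20` and `prog_effect =
effect_for_auc(0.76) ≈ 1.00`. With ~20–57 ratios per panel the latent
score is recovered almost noiselessly, so a well-trained classifier's
external AUROC concentrates near the analytic target; measured over 25
seeds the means are 0.940 (diagnosis) and 0.78 (staging).

The staging score deliberately shares variance with residual severity
(loading 0.5): progression biology is continuous, and this reproduces the
qualitative finding that the progMS probability independently predicts
follow-up disability in a multivariate model. The sharing leaves the
staging score's class-conditional law untouched, so it does not affect
AUROC calibration.

### Assay-level structure

Per-protein intercepts (log-RFU ≈ 7 ± 0.5), age slopes (SD
`age_slope_per_protein = 0.005` log-RFU/year) and sex offsets (SD
`sex_offset_per_protein = 0.05`) are deterministic functions of a hash of
the protein identifier, not of the cohort seed. This makes them
properties of the assay/biology shared by every generated cohort, so a
healthy-reference cohort generated under a different seed estimates the
same adjustment model that applies to the disease cohorts. Beyond the
panel proteins, 200 exchangeable noise proteins (configurable) fill out
the wide table; no attempt is made to mimic 1,305 realistic marginal
distributions.

### Disability timelines

Baseline disability is latent:
`EDSS_true = clip(2.0 + 0.8·s + 0.03·(age − 40) + N(0, 0.5), 0, 9)`.
The *measured* baseline adds retrospective chart-review noise
(`baseline_edss_noise_sd = 1.4` EDSS points) before grid rounding — free-
text neurological examinations transcribed years later are far less
precise than a structured prospective exam (`edss_noise_sd = 0.4` at
follow-up). The MRI-derived baseline estimate sits in between
(`mri_noise_sd = 0.7`), which reproduces the observed pattern that an
imaging-based baseline predicts follow-up disability better than the
retrospective clinical one.

Progression runs on the continuous CombiWISE scale through the ground-
truth monotone quadratic `q(cw) = 0.06·cw + 0.0004·cw²` (EDSS 0–10 over
CombiWISE 0–100): `cw_follow = cw_base + slope_cw · interval`, with
`slope_cw = 0.2 + 0.5·msdss_true + N(0, 0.4)` CombiWISE units/year,
`msdss_true = 1 + 0.5·s`, a configurable 20% of non-progressors whose
slope is zeroed, and follow-up intervals `N(10.2, 5.0)` years truncated
at 0.5. The slope noise leaves severity explaining ~30% of slope
variance, matching the moderate severity↔progression correlation
(r ≈ 0.5) reported for the cohorts these models come from; the severity→
ratio coupling (`severity_coupling = 0.03`) is sized so the CSF-predicted
severity correlates with the true score at r ≈ 0.55 rather than being a
noiseless readout. Measured EDSS values land on the clinical grid: {0}
then half-point steps from 1.0 to 10.0, nearest point, half-up, with the
(0, 1) interval splitting at 0.5.

Conventional markers use class-conditional Bernoulli rates read from the
validation cohort's observed proportions (OCB+ ≈ 0.80/0.79/0.25/0.02,
IgG-elevated ≈ 0.59/0.50/0.24/0.02 for RRMS/progMS/OIND/NIND), with
availability masks (≈93% in MS, 50% in controls) so the marker-comparison
subcohort resembles the real one. sCD27 and NFL are lognormal with
MS-elevated means; attrition removes baseline EDSS for 7 and follow-up
EDSS for 5 MS participants and limits MRI to 54 (counts configurable).

### What the generator does not emulate

Plate/batch effects and normalization artifacts; realistic marginal
distributions for off-panel proteins; center-specific effect sizes
(centers differ only in class mix); longitudinal within-person visit
series; treatment effects on progression. Passing tests therefore show
the *pipeline machinery* is correct and calibrated under the stated
generative assumptions — not that the real classifiers achieve these
numbers.

## Feature engineering

Adjustment subtracts the reference-fitted age and sex terms from log RFU
(residualization that keeps the intercept; it cancels in ratios anyway).
Natural log throughout. The healthy-reference fit is per-protein OLS with
an explicit rank check (both sexes, non-constant age required). Panels
are CSV files (`panel,numerator,denominator`); the packaged diagnostic
and staging panels carry the published 21- and 24-protein lists, but the
historical numerator/denominator pairings are not public, so a
documented deterministic default pairing is shipped (chain `p_i/p_{i+1}`
when the ratio count allows, otherwise disjoint pairs plus wrap plus
wider-offset extras) and panels are fully configurable. The severity
panel's 75 protein identities are likewise not public; the packaged
`severity_panel_synthetic.csv` uses synthetic identifiers and exists so
the severity pathway is fully exercisable. Complex-targeting reagents are
single identifiers (`TLR4_LY96`, `LTA_LTB`).

## Classifiers

`RandomForestClassifier` with 500 fully grown trees, √p features per
split, vote-fraction probabilities (identical to leaf-probability
averaging for pure leaves; both modes exposed). No class reweighting by
default; no imputation — a missing feature at prediction is an error.
Out-of-bag AUROC is stored as training metadata. The tie rule at the 0.5
cutoff assigns the boundary to the negative class (conservative for
sensitivity claims). External-validation discipline is structural: models
carry their training cohort's provenance tag and the pipeline refuses to
evaluate on a cohort with the same tag.

A note on cutoff-based metrics: sensitivity/specificity at 0.5 depend on
probability calibration, which in turn depends on training prevalence and
the forest's vote geometry. The package makes no attempt to match any
particular historical model's calibration, so its simulated confusion
metrics (≈0.87/0.86 at the default prevalence) describe a well-calibrated
classifier rather than one with scores skewed toward the positive class.

## ROC inference

Mann–Whitney AUROC via midranks (ties half-credited — vote fractions tie
often). Stratified percentile bootstrap (positives and negatives
resampled separately; 2000 replicates default; BCa behind a flag).
Mason–Graham significance: exact enumeration of label assignments for
pooled n ≤ 12 with the `P(AUC* ≥ observed)` convention; otherwise a
tie-corrected normal approximation with a 0.5 continuity correction
chosen to track the exact enumeration within 0.02 across all two-class
splits of 10 scores. One-sided toward AUC > 0.5 by default (two-sided via
flag). DeLong's paired test uses placement values with the empirical
covariance across the two score vectors; degenerate zero-variance cases
(identical or rank-identical scores) return p = 1. Coverage of the
bootstrap CI was simulated at true AUC 0.8 (100 + 100 per class, 200
seeds): 94.5%.

## Prognostic chain

The severity→slope line is OLS; the CombiWISE↔EDSS map is a least-squares
quadratic whose monotone domain is computed from the fitted coefficients
(where `c1 + 2·c2·cw > 0`, intersected with [0, 100]) with a warning if
the curve turns inside the observed range. Inversion solves the quadratic
and takes the root inside the monotone domain (round-trip error < 1e-9);
EDSS values outside the attainable image clamp to the domain endpoint
with a warning. ΔEDSS is computed as `q(cw_base + Δcw) − q(cw_base)` —
the quadratic-difference mode — because the conversion curve is the
explicitly fitted object; a slope-only linear mode (local derivative at
`cw_base`) exists behind `conversion_mode="linear"` for sensitivity
analyses. Predicted follow-up EDSS is clamped to [0, 10] but *not*
snapped to the half-point grid: predicted per-interval changes are
sub-grid by construction. Negative slopes (improvement) propagate
unchanged. The explained-variance gain is the two-sided t-test on the
added `delta_edss` term in `measured ~ baseline + delta_edss`, identical
to the one-degree-of-freedom nested F-test; when the added column is
constant it is dropped and the gain p is reported missing.

In the pipeline, the severity→slope line is fitted on a *calibration*
cohort disjoint from the severity forest's training cohort, using the
forest's own predictions as the regressor — the line must map predicted
(not true) scores to slopes, and fitting on in-sample predictions would
bias it through overfit residuals.

## Pipeline and reporting

All randomness derives from one integer seed via named substreams, so a
config fully determines the report. Supplementary mode reads a
per-participant results table through a declarative column mapping
(common aliases resolved automatically), rejects unparseable diagnosis
rows with their line numbers, and marks analyses whose inputs are absent
as "unavailable" rather than failing. OCB+IgG combination is scored as
the sum of the two binaries (0/1/2), the minimal monotone combination.
Per-center AUROCs skip centers lacking a class. p-values pass through one
formatting layer (2 significant digits, scientific) for stable report
diffs; report floats are rounded to 6 significant digits.

## Problem sizes

Defaults balance statistical stability against quick iteration: training
cohorts of 150/80/80/80, validation at the study composition 65/31/30/34,
healthy reference n = 150, cross-sectional conversion fit n = 3000,
forests of 500 trees (tests use 100–200), bootstrap 2000 replicates
(tests 150–500). Calibration checks use 25 seeds; coverage checks 200.

## Known limitations

- The acceptance surface is synthetic: agreement with any real cohort's
  printed values requires that cohort's per-participant results table.
- The historical ratio pairings and severity-panel composition are not
  public; packaged panels are faithful to the published protein lists but
  not to the unpublished pairings.
- The MRI→EDSS model is a configurable linear stand-in, not the published
  imaging model.
- Vote-fraction probabilities from finite forests are discrete; at small
  n this produces ties that very slightly lower AUROC relative to a
  continuous score (handled by half-crediting, but a real effect).
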