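# Methods

`panelflow` re-implements, as a tested library and CLI, the computational
chain of a targeted multiple-reaction-monitoring (MRM) plasma-proteomics
workflow: text-exported chromatograms are integrated into peak areas, areas
pass a QC/normalization chain into a sample × protein table of relative
concentrations, and that table feeds univariate biomarker statistics,
multivariate discriminant models (linear SVM with recursive feature
elimination, OPLS-DA), and linear mixed models for longitudinal cohorts.
Everything is exercised on synthetic data whose generators are part of the
package; no instrument data is required.

## Peak integration

Each transition's time–intensity trace is smoothed with LOWESS over the
five nearest points: a locally weighted *linear* regression with tricube
weights, which is exact on linear signals (this is the invariant the unit
tests pin at 1e-9). The peak apex is the maximum of the smoothed signal,
optionally restricted to an expected retention-time window taken from
calibrant injections. Integration bounds descend from the apex until the
smoothed signal falls below `max(baseline + 3·noise_sd, 1% of apex height)`
or rises again by more than ~3 noise SDs (a genuine local minimum).
Baseline and noise are the median and scaled MAD of the first and last 10%
of the window — robust statistics, so a peak eluting near a window edge
does not inflate the baseline. A peak whose apex fails
`baseline + 5·noise_sd` is flagged `no_peak` and its area is missing, never
zero.

Retention-time alignment is a rigid per-sample shift mapping each sample's
apex onto a reference sample's apex (the tallest detected peak by
default). For short gradients with small drift a rigid shift suffices;
no warping is attempted. The final area is the composite trapezoid rule
applied to the **raw** intensities inside the aligned shared window:
smoothing biases peak areas (the noise-free bias is held under 0.5% by
construction), so it only decides *where* to integrate, never *what*.
Peaks covered by fewer than 12 raw points carry a `low_points` flag,
mirroring the acquisition target of ≥12 points per peak.

## QC and normalization

The chain runs strictly in this order; each step is idempotent on its own
output apart from possible additional outlier masks:

1. **Digestion gate** — samples without a yeast-ENO1 quantifier signal
   (the spiked whole-protein digestion standard) are excluded.
2. **Quantifier/qualifier ratio check** — for each peptide the quant/qual
   area ratio is a property of the transition chemistry; cells deviating
   more than 30% (relative, configurable — no published value exists) from
   the peptide's cross-sample median are treated as wrong-peak
   integrations and set missing.
3. **Blank subtraction** — transitions with a nonzero mean blank-injection
   signal have it subtracted, floored at zero (floor events are reported,
   negative areas never propagate).
4. **Internal-standard normalization** — quantifier areas are divided by
   the sample's ALDOA signal (GSTO1 when ALDOA is unavailable; the choice
   between the two standards is not prescribed anywhere, so ALDOA-first is
   this package's convention). The ratio cancels any per-sample global
   factor exactly — a tested invariance. Protein values are the mean of
   their peptides' ratios (the aggregation rule is unstated in the source
   workflow; the mean is the simplest unbiased choice).
5. **Drift correction** — per protein, a LOWESS curve (span 0.5) of value
   versus injection order estimates the slow multiplicative instrument
   drift; values are divided by the trend and rescaled so the protein mean
   is preserved exactly. The multiplicative (divide-by-trend) model
   reflects that MS response drift scales signals rather than offsetting
   them. Study and pooled-QC samples are fitted jointly.
6. **Outlier masking** — values beyond ten *unscaled* median absolute
   deviations from the protein's median are masked (value-level, never
   sample-level). "Ten median deviations" is read literally: the Gaussian
   consistency constant 1.4826 is *not* applied (configurable via `k`).
   A protein with MAD 0 is skipped with a warning.

A detection-rate filter (protein quantified in ≥80% of study samples,
parameterized) is provided to operationalize "consistently and reliably
detected"; the 80% default is this package's choice, not a reproduction of
any published criterion.

## Univariate statistics

Group comparisons use Mann–Whitney's two-sided U test: exact enumeration
for `min(n, m) ≤ 8` with tie-free data, otherwise the normal approximation
with continuity and tie correction (the two branches agree within 0.01 by
n = m = 15). Multiple testing is controlled by Benjamini–Hochberg at
FDR 5%; fold changes are ratios of group means (affected/control), and the
report includes the signed log10 p used in lollipop displays. Clinical
correlations are Spearman's rank correlation, pairwise-complete, with
exact permutation p-values below n = 10 and BH adjustment *within each
clinical variable's family*. D'Agostino–Pearson (n ≥ 20 enforced),
Box–Cox (profile-ML λ), and the pooled-variance Student t support the
parametric side analyses.

## Discriminant models

Proteins are z-scored with the mean and population SD of the **training
rows only**, after replacing missing values by the training median — test
rows never leak into the scaler. The panel model is a linear soft-margin
SVM (C = 1, squared hinge — library defaults, configurable) trained on a
stratified 70/30 split whose seed is a required explicit argument.
Recursive feature elimination removes one feature per step by |weight|;
stratified 5-fold cross-validation (accuracy scoring) chooses the feature
count maximizing the mean CV score. The refit panel is evaluated on the
held-out 30% with ROC (trapezoid AUC) and precision–recall (step-wise AUC)
curves, and on the full cohort by 6-fold stratified CV repeated 40 times
(macro-averaged precision/recall/F1/balanced accuracy, mean ± SD over
repetition means).

A known limitation, measured on this package's own synthetic cohorts:
when the class signal saturates the cross-validated accuracy (strong
and/or correlated markers), the CV score is flat in the feature count and
its argmax is fold-level noise, so accuracy-maximizing RFE tends to return
*minimal* discriminative panels rather than the complete set of
informative proteins. Panel selection should be read as "a sufficient
panel", not "all informative markers".

OPLS-DA is implemented directly (single predictive component plus
orthogonal components via the classical orthogonal-projection scheme on
centered, unit-variance data). With zero orthogonal components it
coincides with 1-component PLS regression — a cross-checked equivalence.
Reported quality metrics are R²Y and a 7-fold cross-validated Q²; the
number of orthogonal components (up to 3) is chosen by maximizing Q².
Class predictions use a **no-class band**: a predicted response within
[0.35, 0.65] on the 0/1 class coding is returned as "unclassified",
reproducing the behaviour of commercial discriminant software that leaves
ambiguous samples without a class; the band is a declared convention of
this package, configurable, not a reproduction of any proprietary rule.
Model significance is a label-permutation test,
`p = (#{statistic_perm ≥ statistic_obs} + 1)/(B + 1)` with B = 1000 by
default, on Q² (OPLS-DA) or mean CV accuracy (SVM). CV-ANOVA p-values are
out of scope (proprietary); the permutation p is the primary significance
measure.

## Longitudinal models

Conditional growth models are linear mixed-effects models
`y = β0 + β1·t + b0_i + b1_i·t + ε` with per-subject random intercepts and
slopes (unstructured 2×2 covariance), fitted by REML via statsmodels'
MixedLM. Boundary solutions (a random-effect variance near zero) get a
Powell polish; a singular covariance triggers a flagged refit with
independent random effects; a single timepoint per subject degrades,
flagged, to a random-intercept model (and to no slope at all if time never
varies). The slope p-value is a likelihood-ratio test of β1 = 0 with both
fits under full ML — REML likelihoods are not comparable across
fixed-effect structures, and the LRT avoids package-specific
degrees-of-freedom approximations. Screening many responses applies BH
across the slope p-values and reports raw and adjusted p.

## Synthetic data generators

The generators define the package's study conditions and emit
machine-readable truth tables; all oracle tests consume only those truths.

**Chromatograms** are pure Gaussian peaks (analytic areas
`A·σ·√(2π)` make them exact oracles; no tailing by default) with lognormal
amplitudes, one rigid RT jitter per sample, multiplicative injection-order
drift, additive Gaussian noise floored at zero, blanks carrying a chosen
fraction of the mean signal, and qualifier peaks scaled by the true
quant/qual ratio. Defaults (σ = 0.05 min, 0.005 min sampling) give ≥ 40
points per peak.

**Cohorts** mirror the study the pipeline targets: group sizes
HC 36 / PD 99 / iRBD 18 / OND 41, 32 proteins of which 8
(GRN, MASP2, HSPA5, PTGDS, ICAM1, C3, DKK3, SERPING1) are informative with
declared directions (e.g. GRN down, C3 up in PD). Protein ratios are
lognormal with within-group log-SD 0.3 (≈30% CV, realistic for
IS-normalized plasma ratios); the informative shift is delivered *exactly*
as a log-scale standardized difference (default 2.0 for PD vs HC, iRBD at
80% of the PD shift, OND unshifted as a specificity control). Within-group
correlation among informative proteins decomposes into a shared
latent-severity factor (loading 0.4) plus an exchangeable residual
correlation (0.3) within the up- and down-regulated blocks; UPDRS-like and
MMSE-like scores are monotone (increasing/decreasing) in the same latent
severity. What the generator does **not** emulate: batch structure beyond
injection-order drift, informative-protein skew beyond lognormality,
missingness that is anything but completely at random, and measurement
error correlated across proteins — so green tests say the *algorithms*
behave as specified under their assumptions, not that real plasma data
satisfies those assumptions.

**Longitudinal cohorts** draw per-subject random intercepts/slopes and
irregular visit times up to 10 years; defaults (54 subjects, 2–4 visits)
give on the order of 146 observations.

## Numerical choices and defaults

| Parameter | Default | Meaning |
|---|---|---|
| `smooth_window` | 5 points | LOWESS window for trace smoothing |
| `drift_frac` | 0.5 | LOWESS span for drift correction |
| `outlier_k` | 10 | MAD multiples for the outlier mask |
| `fdr_alpha` | 0.05 | BH false-discovery rate |
| `test_fraction` | 0.30 | held-out fraction of the 70/30 split |
| `rfe_cv_folds` | 5 | stratified folds inside RFECV |
| `repeat_cv_splits` / `reps` | 6 / 40 | repeated-CV design |
| `n_permutations` | 1000 | label permutations for significance |
| `min_points_per_peak` | 12 | acquisition-quality flag threshold |
| `ratio_tolerance` | 0.30 | quant/qual ratio deviation limit |

Reproducibility: a single configured seed derives per-stage seeds as
`sha256(f"{seed}:{stage}") mod 2^31`, so stages are independently
reproducible and the composite recipe writes byte-identical manifests
(artifact SHA-256 digests, package version, parameter hash) across
identical runs.

Problem sizes used by the test suite and the acceptance script — 1000
null cohorts for FDR calibration, 20 seeds for classifier recovery, 100
permutation-calibration runs at B = 99 (the separable-fixture check uses
the full B = 1000), 100 + 200 mixed-model simulations — were chosen so the
whole suite runs on a laptop-class single core in minutes while keeping
Monte-Carlo standard errors small relative to the asserted bands.

## Known limitations

- Peak bounds and baseline rules are this package's declared contract;
  co-eluting peaks are not deconvolved and peak shapes are not fitted.
- Absolute quantification from calibration curves is out of scope; all
  concentrations are relative IS ratios.
- The RFE panel is a minimal sufficient panel under score saturation (see
  above), and the OPLS-DA no-class band is a convention, so prediction
  "unclassified" rates are not comparable across band definitions.
- Mixed models assume linear trajectories; nonlinear progression and
  time-to-event structure are not modelled.
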