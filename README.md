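# panelflow

A toolkit for targeted **multiple-reaction-monitoring (MRM) proteomics**
of biomarker panels, built for studies that quantify a few dozen plasma
proteins across patient cohorts — e.g. Parkinson's disease (PD) versus
healthy controls (HC), with prodromal (iRBD) and other-neurological-disease
(OND) groups — and follow subjects longitudinally.

It covers the full computational chain after acquisition:

- **Peak integration** (`panelflow.peaks`): 5-point LOWESS smoothing of
  text-exported chromatograms, apex/bound detection, rigid retention-time
  alignment across samples, and trapezoidal integration of the raw signal.
- **QC and normalization** (`panelflow.qc`): digestion gate on the spiked
  yeast-ENO1 standard, quantifier/qualifier ratio check, blank
  subtraction, internal-standard (ALDOA/GSTO1) ratios, LOWESS drift
  correction over injection order, and a 10-median-deviation outlier mask.
- **Univariate statistics** (`panelflow.stats`): Mann–Whitney U with
  Benjamini–Hochberg FDR at 5%, fold changes, Spearman correlations with
  clinical scores (UPDRS, MMSE), normality tests and Box–Cox.
- **Discriminant models** (`panelflow.discriminant`, `panelflow.opls`):
  a linear SVM with cross-validated recursive feature elimination
  (70/30 stratified split), ROC/PR evaluation, repeated 6×40
  cross-validation, PCA, and OPLS-DA with Q²/R²Y, a label-permutation
  test (B = 1000), and an "unclassified" band for ambiguous samples.
- **Longitudinal models** (`panelflow.longitudinal`): conditional growth
  models (random intercepts and slopes per subject) with likelihood-ratio
  slope tests and BH screening across responses.
- **Synthetic fixtures** (`panelflow.simulate`): generators for
  chromatograms, cohorts and longitudinal data with machine-readable truth
  tables, so the whole pipeline is testable without instrument data.

Model-fitting components follow a statsmodels-like shape: a model object
built from data whose `fit()` returns a results object with estimates,
diagnostics and a `summary()`.

## Worked example

Simulate the default four-group cohort (HC 36 / PD 99 / iRBD 18 / OND 41,
32 proteins, 8 informative), discover a panel, and compare groups:

```python
import panelflow as pf

table, truth = pf.simulate_cohort(pf.CohortSimSpec(seed=7))
two = table.subset_groups(["HC", "PD"])

res = pf.train_svm_rfe(two, two.metadata["group"], seed=7, classes=["HC", "PD"])
print(res.summary())
```

```
Linear SVM panel (RFECV-selected)
==================================
classes:           HC (neg) vs PD (pos)
train/test:        94/41 (split seed 7)
selected proteins: GRN, PTGDS, SERPING1
test accuracy:     0.927
test ROC AUC:      0.991
test PR AUC:       0.997
```

The model was trained on the 70% split (94 samples); RFECV kept a minimal
3-protein panel that classifies the held-out 41 samples with ROC AUC 0.99.
Univariate comparisons recover the designed effects with their directions:

```python
comp = pf.compare_groups(two, "PD", "HC")
print(comp.sort_values("p_adjusted").head(5))
```

```
protein_id  u_statistic      p_value   p_adjusted  fold_change      direction
     PTGDS        181.0 1.671405e-15 5.348495e-14     0.553504  up_in_control
  SERPING1       3348.0 6.731489e-15 1.077038e-13     1.807870 up_in_affected
     ICAM1       3282.0 8.584864e-14 6.867891e-13     1.764281 up_in_affected
       GRN        277.0 7.105390e-14 6.867891e-13     0.526489  up_in_control
        C3       3262.0 1.818325e-13 1.163728e-12     1.779103 up_in_affected
```

`fold_change` is mean(PD)/mean(HC): GRN and PTGDS are reduced in PD
(fold change < 1), SERPING1/ICAM1/C3 elevated, matching the generator's
truth table. An OPLS-DA on the same data reports its explained and
cross-validated response variance:

```python
opls = pf.fit_oplsda(two.values, two.metadata["group"].to_numpy(), seed=7)
print(opls.summary())       # R2Y 0.78, Q2 (7-fold CV) 0.74
opls.predict(table.values)  # "HC" / "PD" / "unclassified" per sample
```

## Command line

Every stage is also a `panelflow` subcommand:

```bash
panelflow simulate chromatograms --out sim/ --n-samples 24 --seed 1
panelflow integrate --traces sim/traces.tsv --panel sim/panel.csv \
                    --runsheet sim/runsheet.csv --out areas.csv
panelflow quantify  --areas areas.csv --panel sim/panel.csv \
                    --runsheet sim/runsheet.csv --out features.csv
panelflow stats     --features features.csv --groups PD,HC --out comparisons.tsv
panelflow train     --features features.csv --classes HC,PD --seed 3 --out model.json
panelflow predict   --model model.json --features features.csv --out predictions.tsv
panelflow run       --config run.yaml   # the composite recipe, with manifests
```

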