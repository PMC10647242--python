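# deltarad

Delta-radiomics survival analysis for paired pre-treatment / early-follow-up
CT of lung tumors.

Patients with advanced EGFR-mutant lung adenocarcinoma routinely get a chest
CT before starting a tyrosine-kinase inhibitor and again 6–16 weeks into
therapy.  The *change* in quantitative tumor texture between those two scans
("delta radiomics") carries information about how long the patient will stay
progression-free that neither scan carries alone.  `deltarad` implements that
whole workflow as a tested Python pipeline — from voxels to a risk model —
for methodologists who want to study, stress or extend the approach without
access to clinical images: a synthetic paired-scan cohort generator with a
planted, recoverable hazard signal stands in for the private hospital data.

The pipeline:

1. **Preprocess** — resample to 1 mm³, Z-score normalise, build the 9-band
   stationary wavelet bank (original + LLL…HHH).
2. **Extract** — 593 features per tumor ROI: first-order, GLCM, GLRLM and
   slice-wise LBP per band, plus 3D shape.
3. **Filter** — keep features with test–retest ICC(2,1) > 0.80 under
   emulated re-segmentation.
4. **Delta** — per feature, with pretreat value p, follow-up f and inter-scan
   interval Δt: `(f−p)/p`, `(1/Δt)·(f−p)/p`, `(1/Δt)·(log f − log p)`, or the
   single-timepoint pass-throughs.
5. **Select** — univariate Cox screen, VIF pruning (>5), top-5 multivariate
   coefficients; clinical covariates get their own two-stage screen after
   missForest-style random-forest imputation.
6. **Model & evaluate** — Cox risk scores on a 70/30 stratified holdout:
   Harrell C-index, IPCW time-dependent AUC at 6/9/12/15 months, 100×
   bootstrap with paired t-tests between methods.
7. **Stratify** — Youden-index threshold on the training ROC splits the
   held-out patients into high/low risk; Kaplan–Meier curves, log-rank test,
   Schoenfeld power.

## Worked example

```python
from deltarad import CohortConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    cohort=CohortConfig(n_subjects=120, image_shape=(16, 16, 16),
                        texture_effect_size=1.5),
    n_bootstrap=100,
    seed=30,
)
result = run_pipeline(config)
for method, report in result.method_reports.items():
    print(f"{method:16s} C-index {report.c_index:.3f}")
print("combined clinical+delta C-index", f"{result.combined_report.c_index:.3f}")
print("log-rank p (high vs low risk)", f"{result.stratification['logrank_p']:.2e}")
```

prints (one CPU, ~2 minutes):

```
pretreat_only    C-index 0.535
follow_only      C-index 0.615
delta            C-index 0.694
delta_time       C-index 0.664
delta_log_time   C-index 0.681
combined clinical+delta C-index 0.674
log-rank p (high vs low risk) 2.03e-02
```

Reading: single-timepoint features barely beat chance because each subject's
baseline texture contrast is a nuisance; the three delta methods isolate the
planted texture-change signal and clearly outrank them (which delta variant
comes first fluctuates with the seed at this sample size).  The combined
model folds in the selected clinical covariates, and the Youden-threshold
split separates the held-out survival curves at p ≈ 0.02.

The numbered scripts under `analysis/` run the same stages against persisted
artifacts (`01_simulate_cohort.py` → `05_risk_stratification.py`), each
writing its tables under `results/`.  A thin CLI mirrors them:
`deltarad simulate --out DIR --seed N` and `deltarad run --out DIR --seed N`.

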