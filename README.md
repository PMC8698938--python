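# dynrad

Dynamic ¹⁸F-DOPA-PET-style radiomics for separating high-grade-glioma
progression from treatment-related changes — on fully synthetic phantom
cohorts with known ground truth.

In amino-acid PET of treated gliomas, the standard *static* reading
summarizes the last 20 minutes of a 30-minute acquisition into a single
tumor-to-brain-ratio (TBR) image. The *dynamic* reading additionally uses the
per-voxel time-activity curve (TAC), in particular its time-to-peak (TTP):
progressing tumor tends to peak early and wash out, while treatment-related
change accumulates slowly. This package implements the full analysis chain
needed to test whether radiomic features of TTP maps discriminate better than
radiomic features of static TBR maps — and, because real patient data cannot
be shipped, it also implements the synthetic cohort generator that plants a
known effect (static, dynamic, both, or none) so every claim can be checked
against ground truth.

## What is inside

| Module | Contents |
| --- | --- |
| `dynrad.images` | Image containers (dynamic 4D, parametric 3D, masks), NIfTI + frame-timing I/O |
| `dynrad.phantom` | TAC kinetic model, textured ellipsoidal tumor phantoms, multicentric cohort simulation with planted effects, scanner batch effects and exact per-voxel truth maps |
| `dynrad.preprocessing` | Isotropic resampling, brain reference, 1.6×SUV_mean tumor segmentation, HYPR-LR denoising, smoothing-spline TAC fitting, TBR and TTP parametric images |
| `dynrad.radiomics` | 94 IBSI-style radiomic features (statistics, histogram, local intensity, GLCM, GLRLM, GLSZM, NGTDM, NGLDM from merged 3D matrices) plus 11 morphological features |
| `dynrad.harmonization` | Reference-batch ComBat with deterministic non-parametric empirical Bayes |
| `dynrad.pipeline` | Label dichotomization, z-scoring, correlation-clustering feature reduction, ADASYN, GP Bayesian hyperparameter search, bootstrap evaluation with out-of-bag validation, Wilcoxon model comparison, Shapley attribution |

See `docs/methods.md` for models, conventions and numerical choices.

## Worked example

Simulate a small two-center cohort whose progression signal lives *only in
the kinetics* (earlier time-to-peak for progressors, static TBR untouched),
then compare the dynamic and static feature sets with elastic-net logistic
regression:

```python
from dynrad.phantom import CohortConfig, simulate_cohort
from dynrad import pipeline as pl

cfg = CohortConfig(n_per_center={"A": 20, "B": 12},
                   effect="dynamic", effect_size=1.0)
cohort = simulate_cohort(cfg, seed=42)
table = pl.features_from_cohort(cohort)     # (32, 212): 2x94 radiomic + 11
                                            # morphological + clinical + meta
settings = pl.PipelineSettings(bootstraps=50, budget=10, cv_repeats=2)
res_dyn = pl.run_experiment(table, "dynamic", "elasticnet_lr", settings, seed=7)
res_sta = pl.run_experiment(table, "static", "elasticnet_lr", settings, seed=7)
p = pl.compare_auc_wilcoxon(res_dyn.bootstrap.auc_distribution_test,
                            res_sta.bootstrap.auc_distribution_test)
```

Output of this exact script (train on center A, test on center B, ComBat
anchored on the reference scanner, all transforms fit on training data):

```
dynamic  test AUC 0.985 (95% CI 0.926-1.000), 51 features after reduction
static   test AUC 0.321 (95% CI 0.111-0.593), 41 features after reduction
one-sided Wilcoxon p (dynamic > static): 3.66e-10
```

The dynamic feature set finds the planted kinetic effect; the static set
cannot, because the generator left the TBR distribution of progressors
untouched. Setting `effect="none"` gives test-AUC confidence intervals that
cover 0.5, and `effect="static"` reverses the ranking.

At paper scale use `pl.PipelineSettings.paper_scale()` (1000 bootstraps,
300 search iterations, 20×5-fold CV) and the default cohort size
(55 training-center and 30 test-center subjects at prevalence 61/85).

## Reproduction

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the main computations end to end (feature-count contract, noiseless and
SNR-5 TTP recovery with/without HYPR-LR, ComBat batch-effect removal, and the
full dynamic-vs-static model comparison over three algorithms at desk scale)
and writes the headline numbers as JSON. Identical seeds give identical
output. The test suite, including the acceptance properties, runs with:

```bash
python -m pytest tests/
```
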