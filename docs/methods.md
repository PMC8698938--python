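# Methods

This note records the models, parameters, conventions and numerical choices
behind each module, plus the known limits of the synthetic generator.
Empirical numbers quoted here were all computed with this code.

## Acquisition model and image containers (`dynrad.images`)

A dynamic acquisition is thirty 1-minute frames (frame mid-times 0.5 … 29.5
min). The static image is defined as the mean of frames 11–30, matching the
common late-window static reconstruction of a 30-minute amino-acid PET scan.
Images live on a common 2 mm isotropic grid (default 28×28×28 voxels).
Dynamic data are stored as float32 — the precision of typical reconstructed
PET — while parametric maps and feature math use float64. NIfTI I/O keeps
frame timing in a JSON sidecar.

## Phantom and cohort generator (`dynrad.phantom`)

### Kinetic model

Each voxel's time-activity curve (TAC) is a gamma-variate uptake with
exponential washout:

    c(t) = baseline + amplitude · (t/tp)^r · exp(r·(1 − t/tp)) · exp(−k·(t − tp) for t > tp)

with rise shape `r = 3`, peak time `tp` ∈ [1, 30] min, washout rate `k ≥ 0`.
This family reproduces the qualitative TAC taxonomy used in dynamic
amino-acid PET reading: early peak + washout (progression-like) versus slow
accumulation (treatment-change-like), controlled by a single interpretable
parameter (`tp`). Healthy brain uses a fixed reference TAC (amplitude 0.8,
`tp` = 6, `k` = 0.004, baseline 0.4).

### Tumor phantom

Tumors are ellipsoids with Gaussian-correlated random texture fields for TBR
and TTP, so radiomic texture features are non-degenerate. Two exactness
guarantees are built in:

- **Planted TBR is exact.** Each tumor voxel's curve is rescaled so that its
  late-frame (11–30) mean over the brain reference equals the planted TBR
  value to machine precision.
- **Planted TTP is grid-quantized.** The TTP texture field is rounded to the
  1-minute frame grid (clipped to [2, 29]) before curves are synthesized, and
  the stored truth is the argmax of the noiseless ratio curve on that grid.
  A continuous planted peak halfway between two frames is not representable
  at the protocol's temporal resolution and makes the per-voxel ground truth
  a knife-edge argmax that flips under float32 rounding; quantizing the
  *generator's* truth (rather than loosening the recovery check) keeps the
  recovery task well-posed. The analysis bins TTP at 1 minute anyway, so no
  downstream quantity changes meaningfully (noisy-recovery MAE is unaffected
  to ~0.01 min).

Noise: dynamic frames get Gaussian noise scaled so that the tumor-mean
late-frame signal-to-noise ratio equals `snr_dynamic` (default 10; `None`
disables); static images get relative Gaussian noise (default 5 %).

### Cohort

The default cohort mirrors a two-center study: 55 subjects at training
center A (scanners `vereos`, `biograph6`) and 30 at test center B (`mct`,
`signa`), progression prevalence 61/85. Labels are planted through
progression-free survival in days, dichotomized downstream at < 183 days
(≈ 6 months). The planted effect is selectable:

- `static` — progressors get higher mean TBR;
- `dynamic` — progressors get earlier mean TTP (kinetics only; TBR untouched);
- `both`, `none`.

Scanner batch effects are per-feature-free image-level shift/scale/TTP-delay
perturbations (reference scanner unperturbed), giving ComBat something real
to remove. All randomness derives from one seed via `SeedSequence.spawn`, so
cohorts are reproducible and subjects are independent. `oracle_signal_auc`
reports the AUC of the planted latent effect for sanity-checking.

### Realism and limits

The generator is a *study-condition* simulator, not a digital patient:
ellipsoidal lesions, stationary Gaussian textures, a single-compartment-like
TAC family, Gaussian (not Poisson/reconstruction-correlated) noise, no
partial-volume effect, no motion, no anatomical background structure. It is
realistic enough that segmentation, denoising, TTP estimation, harmonization
and modeling face genuinely noisy, textured, batch-shifted inputs — and
simple enough that every planted quantity has an exact per-voxel truth map.

## Preprocessing (`dynrad.preprocessing`)

- **Resampling**: SimpleITK B-spline for intensities, nearest-neighbor for
  masks, applied per frame for dynamic data.
- **Segmentation**: voxels ≥ 1.6 × healthy-brain SUV mean (threshold
  inclusive), restricted to 26-connected components touching a seed region —
  the standard amino-acid PET tumor delineation rule.
- **HYPR-LR denoising**: composite images over segments 1–8, 8–20, 20–30 min,
  Gaussian smoothing with 9 mm FWHM; each frame is smoothed, divided by its
  smoothed segment composite and multiplied by the sharp composite. Exact on
  spatially constant frames.
- **TAC fitting**: cubic smoothing splines on the 1-min grid with fixed
  smoothing parameter λ = 0.01. The smoother is linear in the data, so its
  matrix is built once (columns = spline fits of identity columns) and applied
  to all voxels as one matrix product — this is what makes per-voxel fitting
  of whole cohorts cheap and exactly deterministic.
- **Parametric maps**: TBR = static/reference within the tumor mask; TTP =
  frame time of the maximum of the fitted voxel-TAC/brain-TAC ratio (earliest
  frame on ties). Voxels whose fitted curve is degenerate are dropped and the
  returned validity mask reflects that.

Measured on the phantom: noiseless TTP maps equal the planted truth exactly;
at SNR 5 the voxelwise MAE is ≈ 3.4 min raw and ≈ 1.8 min after HYPR-LR
(20 replicates).

## Radiomics (`dynrad.radiomics`)

94 intensity/texture features per parametric image plus 11 morphological
features, following IBSI conventions:

- **Discretization**: absolute bin width (floor(v/w)+1), w = 0.1 for TBR and
  1.0 min for TTP — absolute widths keep bins comparable across subjects.
- **Texture matrices**: single merged 3-D matrix per family over the 13
  unique directions (GLCM symmetrized as M + Mᵀ). Families: GLCM (18),
  GLRLM (13), GLSZM (16), NGTDM (5), NGLDM (7); plus statistics (18),
  histogram (15) and local intensity (2). GLSZM zones use 26-connectivity;
  NGLDM dependence counts same-level 26-neighbors (coarseness 0, column k =
  number of dependent neighbors, stored as a (Ng, 27) matrix). Run/zone
  percentage denominators: GLRLM uses Nv·13 (merged directions), GLSZM and
  NGLDM use Nv.
- **Degenerate regions stay finite**: a single-voxel region yields a 1×1
  GLCM [[1]]; NGTDM coarseness is capped at 1e6 (its IBSI-recommended cap).
- **Morphology**: 11 features from the mask — voxel-counted volume, surface
  and derived shape descriptors from a marching-cubes mesh (0.5-voxel
  Gaussian anti-aliasing first, which rounds sharp corners slightly), and
  PCA-based elongation/flatness/axis lengths. Mesh-based values are not
  exactly invariant under axis permutation (triangulation asymmetry, < 2 %).
- Correctness of every texture feature is checked against independent
  brute-force loop implementations (max observed |Δ| ≈ 6e-14).

## Harmonization (`dynrad.harmonization`)

Reference-batch ComBat. Features are standardized using the reference batch's
mean and SD (ddof = 1); per-batch location/scale parameters (γ, δ²) are
shrunk by a *deterministic* non-parametric empirical Bayes step — each
feature's estimate is replaced by the likelihood-weighted average of all
*other* features' estimates (leave-one-out), avoiding the Monte Carlo
integration of classical implementations so results are exactly reproducible.
Reference-batch rows pass through unchanged to machine precision. An
alternative `anchor="grand"` mode harmonizes toward the pooled mean.
Zero-variance features pass through; fitting requires ≥ 2 batches and ≥ 3
subjects per batch; applying to unseen batches or mismatched schemas raises.

On a planted shift+scale scenario (200 features, 30 subjects/batch) the
between-batch F-statistic drops for ≥ 95 % of features while reference rows
change by < 1e-8.

ComBat is fit on the **full** feature table (train + test): it is label-free,
and the test center's scanners do not occur in the training center, so their
batch parameters can only be estimated from their own subjects — this mirrors
multicentric harmonization practice. Every label-aware transform
(z-scoring, feature reduction, hyperparameter tuning, class rebalancing) is
fit on training data only.

## Modeling pipeline (`dynrad.pipeline`)

Order of operations in `run_experiment`:

1. split by center (train = A, test = B); dichotomize PFS at < 183 days;
2. ComBat (full-table fit, reference-scanner anchor) on harmonizable columns;
3. z-scoring with training-population mean/SD (constant features → 0);
4. unsupervised redundancy reduction: complete-linkage clustering of
   1 − |Spearman ρ| cut at correlation 0.9; each cluster is represented by
   the member with highest mean |ρ| to its co-members;
5. hyperparameter search: Gaussian-process Bayesian optimization (Matérn
   ν = 2.5 × constant + white kernel, normalized targets, expected
   improvement over 512 random candidates, 10 random initial points) over
   the per-algorithm spaces (elastic-net logistic regression, random forest,
   XGBoost), scoring repeated stratified-k-fold log-loss with ADASYN applied
   *inside* each training fold;
6. bootstrap evaluation: B resamples of the training set (redrawn if a class
   vanishes), ADASYN rebalancing per resample, refit, metrics on the
   bootstrap sample, its out-of-bag complement and the held-out test set;
   95 % percentile confidence intervals (aggregates rounded to 10 decimals
   before serialization so JSON output is byte-stable);
7. attribution: XGBoost native Shapley contributions, or Monte-Carlo
   permutation-sampling Shapley values for the other models, summarized into
   provenance shares by feature prefix (clinical / static / dynamic /
   morphology).

Model comparison uses one-sided Wilcoxon signed-rank tests on paired
bootstrap test-AUC distributions, Benjamini–Hochberg corrected. ADASYN and
the GP search are implemented in-package (deterministic, seeded via
`SeedSequence`); ADASYN balances classes exactly by largest-remainder
apportionment and reduces k with a warning when the minority class is tiny.

`PipelineSettings` defaults are desk-scale (100 bootstraps, 30 search
iterations, 3×5-fold CV); `PipelineSettings.paper_scale()` switches to
1000 bootstraps, 300 iterations and 20×5-fold CV. Feature sets:
`clinical`, `tbr_mean`, `clinical+tbr_mean`, `static` (TBR radiomics +
morphology), `dynamic` (TTP radiomics + morphology), `static+dynamic`.

## Limitations

- The phantom's texture and noise models are Gaussian and stationary; real
  PET noise is count-dependent and reconstruction-correlated, and real
  lesions are not ellipsoids. Absolute feature values should not be compared
  to clinical cohorts; only the *relative* behavior of pipelines is
  meaningful here.
- Scanner effects are affine image-level perturbations; real inter-scanner
  differences include resolution and point-spread differences ComBat cannot
  fully describe.
- The smoothing-spline λ and the HYPR-LR parameters are fixed protocol
  choices, not optimized per subject.
- Desk-scale defaults trade statistical resolution for runtime; conclusions
  at paper scale require `paper_scale()` and the default cohort size.
- Mesh-based morphology carries a small (< 2 %) anti-aliasing/triangulation
  bias; voxel-counted volume is exact.
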