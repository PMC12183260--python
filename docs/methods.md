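# Methods

## Problem setting

`scnpipe` re-implements, as a tested pipeline, the comparison of two
*individual* structural-covariance-network (SCN) estimators against plain
regional gray-matter volume (GMV) for case–control classification of a
psychotic disorder. Group-level SCNs — region × region correlations of a
morphological property across subjects — cannot support individual
prediction; the two individualizations used here are:

- **REF-SCN** (reference contribution). Given a healthy reference cohort
  with regional GMV table `X_ref`, the network of individual *i* is
  `W_i = corr(X_ref ∪ x_i) − corr(X_ref)`, element-wise. Adding one
  subject to a reference of n subjects perturbs each correlation by
  O(1/n); the matrix of perturbations is that subject's deviation
  fingerprint. Entries lie in [−2, 2]. The sign convention (positive =
  the individual increases the reference correlation) is a documented
  choice; classification is sign-agnostic.
- **KLS-SCN** (symmetric Kullback–Leibler). For one subject, the edge
  between parcels *i* and *j* is `KL(p_i‖p_j) + KL(p_j‖p_i)` where `p_r`
  is a Gaussian-kernel density estimate of the parcel's voxel-wise GMV
  values. This needs no reference cohort; it measures how different the
  two parcels' voxel-value distributions are *within* the subject.
  Entries are ≥ 0.

From each network we derive edge features (upper-triangle vectorization,
d(d−1)/2 values) and metric features (3d+2 values: per-node strength,
eigenvector centrality, local efficiency; global efficiency;
transitivity).

## Density estimation and divergence

`estimate_pdf` evaluates a Gaussian KDE on a fixed grid and returns a
discrete probability mass (floored at 1e-12, renormalized), so the
divergence is a finite sum over grid masses. Bandwidth is Silverman's
rule `0.9·min(sd, IQR/1.34)·n^(−1/5)` per parcel. For a parcel pair the
grid has 128 points spanning the pooled min–max extended by three pooled
bandwidths on each side. Consequences worth knowing:

- the divergence depends (weakly) on sample size through the bandwidth, so
  duplicating every voxel changes edges by a few percent (edge vectors
  correlate > 0.99); exact duplication invariance would require an
  n-free bandwidth;
- zero-spread parcels are an error, not a silent degenerate density.

A quadrature sanity value: discretized N(0,1) vs N(1,1) on a fine wide
grid gives symmetric KL = Δμ²/σ² = 1.0.

## Graph metrics

Weighted connectivity-toolbox conventions: shortest paths on edge lengths
1/w (Dijkstra; missing edge = no path; unreachable pairs contribute 0 to
efficiency); transitivity = trace(W^(1/3))³-style geometric-mean triangle
intensity over Σk(k−1); local efficiency of a node = global efficiency of
its neighbor-induced subgraph; eigenvector centrality by power iteration
(tolerance 1e-10) on `W + max(W)·I` — the positive diagonal shift leaves
eigenvectors untouched but makes the Perron value strictly dominant, so
bipartite components converge instead of oscillating. Because REF-SCN
edges can be negative, weights are mapped to [0,1] by absolute value and
max-normalization before any metric (configurable to clip-at-zero
instead). No density thresholding is applied.

## Classification design

Repeated nested pooled CV: P2 outer permutations × K2 stratified outer
folds, K1 inner folds inside each outer training partition. The reference
configuration is 10/10/10; the synthetic experiments in this package run
at desk scale (K2=5, K1=3–5, P2=1–2) — the logic is identical, only the
averaging is lighter. Two branches per modality:

- **LASSO branch**: covariate residualization (per-feature OLS on
  [1, age, sex], coefficients frozen on the training side) →
  feature-wise z-scoring → L1-penalized squared-hinge linear SVC
  (liblinear; the L1 penalty is only available with the squared hinge,
  so that loss is used for this branch).
- **PCA branch**: residualization → PCA (n_PC on the grid {5,10,15,20,25})
  → z-scoring of component scores → L2 hinge SVC.

C is optimized on {2^x, x = −6..4} by mean inner-fold balanced accuracy
(pooled-prediction BAC available behind `pooled_predictions=True`); ties
prefer the smaller C, then the smaller n_PC (more regularization). Class
weights are inverse class frequencies ('balanced'). The winning
configuration is refit on the full outer training partition and scored on
the outer test fold; per-subject grand-mean decision scores average
out-of-fold scores over permutations, and the class rule is score ≥ 0 →
patient. Zero-variance features pass through standardization as zeros.
All preprocessing statistics are estimated strictly on training subjects.

**Stacking.** The meta-classifier (L2 hinge SVC, same C grid) is trained,
inside the identical CV structure, on the base models' *inner
out-of-fold* decision scores: the meta training feature of subject s is
the score produced by a base model fit while s was held out in an inner
test fold; meta test features are the base models' outer-test scores.
Every score carries provenance (which inner fold produced it), and
`stack()` audits this against the CV plan before training — a swapped or
in-fold score raises `LeakageError`. Stacker results carry the same
provenance, so modality-level stackers can feed a higher-level stacker.

**Attribution.** Model weights are mapped back to input-feature space
(dividing by the standardization scale and, for the PCA branch,
back-projecting through the component basis), so importance maps are
comparable across branches. Two stability measures over the M = P2·K2
refit weight vectors: the cross-validation ratio mean/SE (median variant
for regressions; SE = SD/√M; zero-SE nonzero-mean features get a capped
±1e6 sentinel and a flag) and sign consistency — an exact two-sided
binomial test of the positive-weight count against 0.5, BH-corrected,
flagged at −log10(adjusted p) > 1.3. For sparse L1 models only nonzero
weights count as trials (default `zero_policy='exclude'`): a feature the
model never selects is irrelevant, not consistent; the literal all-M
counting is available as `zero_policy='count'`. Regional involvement is
the degree of each region in the significant-edge network.

**Significance and comparison.** Model p-values use label permutations
with the add-one estimator (B configurable; 99 at desk scale), reusing
the identical CV plan per replicate. Model comparison across CV blocks
(outer fold × permutation cells) uses the Quade rank test with an
F(k−1, (b−1)(k−1)) reference, followed by *paired* t-tests (the blocks
are shared) with Benjamini–Hochberg correction. Cohort effects on
decision scores are tested by a two-sample t-test plus OLS
`score ~ cohort + age + sex`.

**External calibration.** A validation cohort is calibrated to training
by adding per-parcel offsets `mean_train − mean_valid` to its regional
GMV (idempotent). Because SCN features should be recomputed after
calibration, the offsets can be propagated to voxel level uniformly
(each voxel of parcel r shifted by offset_r/n_vox,r) — the minimal
voxel-level change consistent with the regional shift.

## Clinical score regression

A linear ε-insensitive SVR predicts imaging decision scores from patient
clinical features inside the same nested CV: median imputation and
z-scoring frozen per training partition; C on the shared grid and
ε ∈ {0.01, 0.1, 0.5} selected by mean inner R²; out-of-fold grand-mean
predictions; R² (percent, 1 − SSE/SST, can be negative) and MSE reported
on the globally z-scored target so scales are comparable across imaging
models. Importance uses the median-based CV ratio; maps from two models
are compared by Pearson correlation of those vectors.

## Synthetic cohorts

The generator draws, for subject s and parcel r, voxel values
N(μ_sr, voxel_sd²) clipped at zero, with

    μ_sr = baseline_r + λ_r·z_s + ε_sr + site_r/n_r + age/sex terms
           + global_shift/n_r ,

z_s ~ N(0, I_q) shared latent factors (default q=5, loading scale 0.03
on per-voxel means around baselines of ~0.45–0.65), ε_sr ~ N(0, 0.05²),
voxel_sd = 0.1. Patients receive (a) a regional mean reduction of
`mean_effect` standard deviations of regional GMV on affected parcels,
scaled by a per-patient latent severity u_s ~ N(1, 0.3) truncated at 0.1,
and (b) a rotation of the affected parcels' loading vectors by
`cov_effect` radians toward a random orthogonal direction — this changes
inter-parcel covariance while *preserving* each parcel's marginal mean
and variance, so covariance effects are separable from mean effects by
construction. Site effects and external-cohort offsets are additive on
the regional scale. The model-implied regional covariance has the closed
form `N(ΛΛᵀ + σ²I + covariate terms)N + diag(n·voxel_sd²)` (N = diag of
voxel counts), which the empirical covariance of a 2000-subject cohort
reproduces within 10% relative Frobenius error.

Clinical tables couple each feature to the standardized severity with
correlation `clinical_coupling × loading`; BMI and the affect-related
SANS items carry the largest loadings, so severity-coupled decision
scores are predictable from clinical features by construction, with BMI
the strongest planted driver.

What the generator does *not* emulate: 3-D geometry, smoothing,
scanner physics, heavy-tailed voxel distributions, non-linear covariate
effects, missingness mechanisms. Passing tests therefore demonstrate
correctness of the estimators and the leakage-free design under a
Gaussian latent-factor world, not performance on real MRI.

## Experiment problem sizes (desk scale)

- Null/signal calibration: n=400 (200/200), d=100, LASSO branch,
  K2=5/K1=3/P2=1, B=99 permutations. Null BAC lands in [45,55]% with
  non-significant p; a 1.5 SD reduction on 10% of parcels gives BAC > 90%
  at p = 0.01.
- Covariance-only complementarity: d=24 (compact parcellation, voxel
  counts 30–80), n=300, healthy reference n=150 across 2 sites
  (harmonized), rotation angle calibrated by bisection toward mean
  |Cohen's d| = 1 on affected REF edges. The per-edge d' saturates below
  1 even at the π/2 cap — a single subject's contribution to a reference
  correlation is noisy relative to the group shift — but the *multivariate*
  edge signal is strong: REF/KLS edge models reach ~83% BAC while
  regional GMV stays at chance (rotation preserves marginals), and the
  stacked model tracks the best base model.
- Attribution recovery: 435 edge features (d=30), 20 planted edges at
  1 SD, n=400, M=20 weight vectors; sign consistency flags all planted
  edges with ≈0.2% false flags.
- Clinical recovery: n=150 patients, target = 0.4·BMI_std + N(0, 0.9²)
  (generative truth 16.5% variance explained), the 7 continuous
  demographic/illness features, coupling off. Measured out-of-fold R²
  ≈ 5–13% across seeds with BMI ranked first. Binary/symptom noise
  columns are excluded from this fixture: within the fixed C grid their
  chance correlations dominate an L2 SVR at n=150, which would measure
  feature-count attenuation, not recovery.

## Known limitations

- REF-SCN recomputes the full augmented correlation matrix per subject
  (O(n·d²) each); fine at these scales, vectorizable if needed.
- The KLS estimator loops over parcel pairs; d=200 and large voxel
  counts are minutes per subject.
- Sign consistency assumes weight signs are exchangeable across CV
  models under the null; strongly correlated folds make it liberal,
  which the FDR correction only partly absorbs.
- The permutation test reuses the CV plan rather than redrawing folds
  per permutation; with stratification broken by permuted labels this is
  slightly conservative.
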