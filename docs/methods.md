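# Methods

This note documents the models and procedures implemented in `radsurv`, the
parameter choices that matter, the design decisions taken where several
reasonable options existed, and the known limitations. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohort

The generator provides ground truth for an analysis pipeline whose original
clinical cohort is not publicly available. It emulates three ingredients:

**Tumor phantoms.** The mask is an ellipsoid (semi-axes a ≥ b ≥ c, mm) whose
surface radius is modulated by a random real spherical-harmonic field of
degree 2–4 scaled by `lobulation_amp` (fraction of radius). Low-order
harmonics tune compactness smoothly without fragmenting the mask; the
largest connected component is kept as a safeguard. The in-mask texture is
white noise convolved with an isotropic Gaussian of `texture_corr_mm`
(mm), rescaled to the requested intensity mean/SD (HU-like, default
40 ± 12 over a lung-like −800 ± 30 background). One knob
(`texture_corr_mm`) therefore controls the local-homogeneity features
(GLCM IDMN) and one (`lobulation_amp`, with anisotropy) controls shape
compactness. Default grid 64³ at 1 mm so resampling is near-identity; the
acceptance runs use 48³ to keep cohort extraction inside a few minutes.

**Clinical covariates.** N stage (0–3), M stage (0/1a/1b/1c), histology
(adeno / non-adeno), total protein and mean corpuscular volume (with an
explicit `missing` level) and smoking status are drawn independently from
the published marginal frequencies of a 270-patient EGFR-TKI cohort
(`TABLE1_COUNTS`). Stage entries recorded as "not available" are
redistributed over the observed levels; laboratory variables keep
`missing` as an informative-free category.

**Outcomes.** PFS follows Weibull proportional hazards:
T = λ₀·(−log U / exp(η))^(1/k₀) with η the linear predictor of the true
log-hazard coefficients on cohort-standardized covariates (mask
compactness₂, texture correlation length, ordinal N and M stage, non-adeno
indicator). Censoring is uniform on (0, admin cap) — the emulated study
reports no censoring mechanism, so uniform plus an administrative cap is
the neutral choice; the censoring proportion is a calibration choice, not a
reported fact. Defaults k₀ = 1.3, λ₀ = 20 months, cap 72 months, and
coefficients (−0.8 compactness, +0.5 texture, +0.45 N, +0.45 M, +0.3
histology) were calibrated once by simulation so the realized cohort sits
in the regime the pipeline targets: event fraction 0.6–0.9, median PFS in
the 8–15-month band around the ~11.5-month regime, and enough signal that
the combined model is separable from the single-view models. Signs follow
the reported clinical directions: rounder tumors (high compactness) and
less homogeneous texture progress later; higher stage progresses earlier.

An image-free path (`simulate_tabular_cohort`) replaces the two
imaging-derived covariates with latent standard-normal scores and appends
pure-noise columns. Model-level tests (null-signal calibration at n ≥ 1000,
oracle comparisons) use it because those properties concern selection and
training, not image feature extraction.

**What the generator does not emulate:** lung anatomy and vasculature,
contrast phases, scanner/kernel variation, multi-lesion disease, correlated
clinical covariates, and informative censoring. Passing tests demonstrate
that the *pipeline* recovers planted effect structure under the stated
noise model — not that it attains any particular performance on real CT.

## Preprocessing

Resample to isotropic 1 mm³ (trilinear intensities, nearest-neighbour
labels, re-binarized), Z-score over the whole volume (not ROI-only), then a
one-level **undecimated** separable wavelet transform (Coiflet-1 analysis
filters via `scipy.ndimage.correlate1d`, reflect boundary) giving the eight
L/H subbands on the input grid. Undecimated filtering keeps mask–subband
alignment, which the per-subband texture features require; the wavelet
family, level count and decimation are this package's conventions, chosen
where the emulated procedure left them unstated. Processing order is
resample → normalize → filter.

## Radiomic features

Exactly 593 features per ROI: per image set (original + 8 subbands),
14 histogram, 22 GLCM, 16 GLRLM and 12 LBP features (9 × 64 = 576), plus
17 geometry features computed once on the original-resolution mask. The
inventory is a standard IBSI-aligned panel realizing the printed total and
containing the features the analysis depends on (IDMN, compactness₂);
the exact published membership is not available, so membership is this
package's convention. Conventions worth noting:

- **Discretization**: fixed bin number (32) over the in-mask min–max range —
  robust to the Z-scored intensity scale. A constant ROI collapses to one
  level; degenerate features then take their uniform limits (IDMN = 1,
  contrast = 0, entropies 0) and are flagged in metadata.
- **GLCM**: distance 1, 13 unique 3-D directions, matrix-level
  symmetrization, features computed on the direction-averaged matrix.
  Entropies use log₂.
- **GLRLM**: per-direction run matrices, features averaged over directions.
- **LBP**: rotation-invariant uniform codes (P = 8, R = 1, 10 bins) per
  axial slice, pooled over slices; features are the normalized histogram
  plus its mean and entropy. Border pixels without a full neighbourhood are
  excluded.
- **Histogram**: population moments; kurtosis is the plain fourth
  standardized moment (Gaussian → 3).
- **Geometry / surface estimation**: marching cubes on the binary mask
  over-estimates the area of smooth surfaces by ~8% (staircase facets),
  while any pre-smoothing rounds genuinely sharp edges. The package
  therefore meshes an anti-aliased field (separable triangle kernel, which
  leaves flat axis-aligned faces exactly on the voxel boundary) and
  switches to the convex hull of the voxel corners when the hull lowers
  compactness₂ by more than 5% — possible only for effectively convex
  masks with flat faces, where the hull *is* the exact boundary. Hulling a
  bumpy mask always raises compactness, so lobulated tumors never take the
  hull branch and the shape signal is preserved. With this estimator a
  digitized ball measures compactness₂ ≈ 0.98 and a voxel cube exactly
  36πV²/A³ = 0.5236. Axis lengths use 4·√(eigenvalue) of the voxel-centre
  covariance.

A known artefact: with a high-contrast background (lung at −800 HU), the
ROI-boundary intensity step leaks into low-pass subbands and can dominate
in-mask texture features computed there; texture-direction tests therefore
validate the homogeneity ordering on the original image set and on
subbands with matched background.

## Feature selection

Training split only. Radiomic features are standardized (train mean/SD) and
screened by univariate Cox proportional hazards (Wald p < 0.1); clinical
categories by Pearson chi-squared against the good/poor tumor-control
dichotomy at the training-median PFS, with patients censored before the
median excluded as indeterminate. The permissive 0.1 threshold keeps enough
inputs for the network. Screened radiomic features are ranked by p-value
and the strongest 25 enter sequential forward selection; SFS runs
separately on the clinical and radiomic pools (default cap 5 each, union =
combined panel), scored by 5-fold cross-validated concordance of a lightly
penalized Cox fit with seeded folds. A Cox scorer rather than repeated
network training keeps the search deterministic and tractable.

Stopping: an addition must improve the running score by ≥ 0.01, and the
empty model scores 0.5 (the concordance of a constant predictor). The
tolerance is set at the scorer's noise floor because greedy selection
maximizes a noisy estimate over many candidates and a literal ~1e−4
tolerance grows panels on pure noise; with these rules the median panel on
noise-only pools is ≤ 2 while a genuinely prognostic feature is selected
first.

## Risk model

A feed-forward log-hazard estimator. Hidden blocks apply, in order, batch
normalization (learnable scale/shift) → ReLU → fully connected → dropout;
the output is a single linear node, so zero hidden blocks reduce exactly to
the Cox linear predictor. Because that block order normalizes the *input*
features before the ReLU, half of every standardized input would be clipped
at initialization; the batch-norm shift is therefore initialized at +1 so
units start in their linear regime (the shift remains learnable).

Loss: average negative log Cox partial likelihood with Breslow handling of
tied event times plus an L2 penalty on the connection weights, computed
with a cumulative log-sum-exp for stability. Training is full-batch Adam —
risk sets are then exact and batch-norm statistics cover the full batch —
with learning rate lr₀/(1 + decay·epoch) and early stopping on an inner
80/20 validation split (stratified by event), restoring the best-epoch
weights. Defaults: 1 hidden block of 32 nodes, dropout 0.40, lr 0.01,
decay 0.01 (the emulated study's stated values); λ = 1e−4, 500 epochs,
patience 50 (unstated there; chosen for desk-scale convergence).
Gradients are analytic (manual backprop) and verified against central
finite differences to 1e−5. `grid_search` scans layers × nodes × lr ×
decay × dropout, selects by inner-validation concordance, and breaks ties
toward fewer parameters then lower learning rate.

The Breslow estimator H₀(t) = Σ_{tₖ≤t} dₖ / Σ_{j∈R(tₖ)} exp(hⱼ) supplies
the baseline survival S₀ = exp(−H₀) (a right-continuous step function);
personalized curves are S(t|x) = S₀(t)^exp(h(x)), evaluated by step
interpolation on a monthly grid to 30 months. With all scores zero this
reduces exactly to the Nelson–Aalen-based survival.

## Evaluation

**Harrell's C** counts pairs whose strictly earlier observed time is an
event; score ties count ½; tied observed times are not comparable. The
implementation is checked against exhaustive pair enumeration and against
lifelines on tie-free data.

**Time-dependent ROC** uses the cumulative/dynamic definition: at horizon
t, cases progressed by t, controls progression-free past t, censored-
before-t excluded. The marker is S(t) (low ⇒ progressed); because S(t|x)
is a monotone transform of h(x), marker choice does not affect AUC. The
operating threshold maximizes the Youden index. Censoring-exclusion rather
than IPCW weighting is the default; at the simulated censoring rates the
exclusion bias is small relative to test-split noise.

**Model comparison** bootstraps the test set (default B = 1000; B is a
runtime choice in tests and the acceptance script), shares replicate
indices between models, recomputes AUC/sensitivity/specificity per horizon
per replicate, redraws replicates lacking cases or controls at some
horizon, and applies a paired t-test per metric. The **log-rank** test
follows the predicted-risk median-split convention (observed outcomes
between predicted groups), the less ambiguous of the two readings of
"difference in average personalized curves".

## Reference risk curve and risk periods

The four (horizon, S*) anchors are fitted by least squares on the
complementary log-log linearization log(−log S*) = k·log t − k·log λ —
exact and deterministic, recovering (k, λ) identically when the anchors lie
on a Weibull curve; anchors implying non-decreasing survival are rejected.
Patient curves are compared with S_ref on a 0.5-month grid over the
[0, 24]-month window (the latest evaluation horizon): the signed and
negative-part areas are both reported, sub-intervals with S_patient < S_ref
are located by linear sign-change interpolation, and the category is the
checkpoint-partition interval (<3, 3–12, 12–18, 18–24, >24 months)
containing the earliest crossing. Classification is monotone: uniformly
lowering a curve never moves the category later.

## Pipeline

One stratified 70/30 split (strata: censored / event below median / event
above median; ⌊0.7·n⌋ training patients) and one seed set are shared by the
three model variants so paired comparisons are valid. Clinical encoding: N
and M stage as ordinals 0–3, histology as a non-adeno indicator,
laboratory variables as category indicators with explicit `missing`,
smoking as an indicator. Artifacts (feature matrix, screen results, panels,
model bundles as JSON, metrics, per-patient risk reports, reference-curve
parameters) are written under the output directory with a provenance
manifest of configuration and seeds; a rerun with the same manifest
reproduces the results bit-for-bit.

## Problem sizes

Unit tests use cohorts of 60–400 patients (images only where needed) and
40³–64³ grids. The parameter-recovery checks and the acceptance script use
the default 270-patient cohort on 48³ grids with a 5-seed split batch and
bootstrap B = 200–500; package defaults elsewhere are 64³ and B = 1000.

## Limitations

- The 593-feature membership reproduces the printed family counts, not a
  published list; absolute feature values depend on the stated
  discretization and estimator conventions.
- Phantoms are single smooth lesions on homogeneous noise; selection
  frequencies and effect sizes on real CT will differ.
- The time-dependent ROC excludes censored-before-horizon patients rather
  than IPCW-weighting them.
- The Weibull reference curve assumes the four thresholds decrease with
  horizon; very noisy small test splits can violate this, in which case the
  reference curve (and risk periods) for that variant are skipped with a
  logged warning.
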