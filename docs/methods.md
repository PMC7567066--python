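# Methods

`painnet` implements a connectome-based model of longitudinal pain-intensity
change in subacute back pain (SBP): from each patient's baseline
resting-state fMRI it builds a network-level functional connectome, selects a
sparse, stable set of connections predictive of the time-normalized change in
the 0–100 visual analog scale (VAS), predicts each patient's VAS trajectory
over roughly one year, and classifies patients into persistent (SBPp) versus
recovering (SBPr) groups. This note documents the model, its assumptions,
the tunable parameters, and the synthetic study design used to validate every
stage.

## Pipeline model

### Network definition (group spatial ICA)

Baseline volumes from all subjects are temporally concatenated and decomposed
by spatial ICA: voxels are the statistical samples, so the factorization
yields K spatially independent maps with shared mixing time courses — the
standard group-ICA formulation. Dimension reduction to model order K happens
in the whitening step (PCA on the concatenated data). The ICA sign ambiguity
is resolved by forcing each map's maximum-magnitude voxel positive, and
non-convergence triggers up to three deterministic restarts before an error.

Components are labelled by spatial cross-correlation against template
resting-state-network maps over in-mask voxels after de-meaning (absolute
value, since the sign is arbitrary). A component whose best |r| is below 0.1
is flagged as noise and excluded; the manual visual-inspection step used in
practice is replaced by an optional keep/drop list applied after matching.
Anatomical annotation uses atlas-region overlap: a region is "involved" when
|region ∩ component mask| / |region| strictly exceeds 0.9, with component
masks thresholded at |z-scored weight| > 3 (a conventional display threshold;
configurable).

Per-subject component time courses come from stage-1 dual regression: at each
time point all kept maps are regressed jointly onto the volume. How subject
series were extracted is genuinely open in this design; dual regression is
the documented choice because it is the field's standard and is exactly
invertible on noiseless mixtures, which gives the tests a closed-form oracle.

### Connectivity

For a subject's T × N component series the connectome is the ridge-
regularized partial correlation: with C the sample correlation matrix and
P = (C + ρI)⁻¹,

    partial_r(i, j) = −P_ij / √(P_ii · P_jj),   ρ = 0.01 by default.

Regularization is applied to the correlation rather than covariance matrix so
ρ is scale-free across components (the toolbox dialect this mirrors does not
document its internal scaling; this choice is pinned down here and can be
emulated with pre-scaled data if the covariance dialect is wanted). Edges
are Fisher r-to-z transformed and vectorized in row-major upper-triangle
order, E = N(N−1)/2 per subject. An optional residualization of each edge on
the sex covariate (OLS with intercept; idempotent) supports the
sex-controlled variant.

### Feature selection (LASSO-in-LOOCV stability rule)

The prediction target is the normalized VAS slope
(VAS₄ − VAS₁)/Δt₁₄ in VAS/day. For each of M leave-one-out folds a LASSO is
fitted to the remaining M−1 subjects; the penalty is chosen by inner 10-fold
CV under the minimum mean-squared-error rule. Edges with nonzero coefficients
in strictly more than 75% of the M fits are the final feature set.

Three details the procedure's description leaves open are fixed as follows:

* features are standardized on each training fold (LASSO is scale
  sensitive); supports are reported against original columns;
* the penalty path is 100 log-spaced values from the data-driven maximum
  λ_max = max|Xᵀ(y − ȳ)|/n down to 10⁻⁴ λ_max, with exact CV ties resolved
  toward the larger (sparser) penalty;
* inner folds are shuffled with a seed derived from the held-out subject's
  ID, and training rows are ordered canonically by ID first, so the
  selection frequencies are invariant to the order subjects appear in the
  table.

The stability tally counts an edge's nonzero status at the CV-optimal penalty
of each fold only (not anywhere on the path).

### Prediction and scoring

The selected edges feed a plain OLS model (intercept included) predicting the
normalized slope under LOOCV; the edge set is frozen — only coefficients are
refitted per fold. LOOCV predictions are computed through the exact
hat-matrix leave-one-out identity, ŷ₋ᵢ = yᵢ − eᵢ/(1 − hᵢᵢ), which is
algebraically identical to refitting per fold at a fraction of the cost; the
explicit per-fold refit is kept as the independent oracle in the tests. With
zero selected edges the model degenerates to intercept-only, predicting each
fold's training mean (note r(actual, predicted) = −1 identically in that
degenerate case, since the training mean decreases in the held-out value).

The single predicted slope extrapolates to any visit:
ΔVAS₁ₙ = slope × Δt₁ₙ and VASₙ = VAS₁ + ΔVAS₁ₙ, so the three visits' predicted
changes are exactly proportional (single-rate linearity — an invariant the
tests assert at machine precision).

Per target (slope, ΔVAS and VAS at visits 2/3/4) the model reports Pearson r
and RMSE. RMSE is reported on the normalized-slope scale (VAS/day), where
values of ~0.02–0.2 are natural given slope spreads of ~0.1 VAS/day;
raw-scale errors are recoverable from the per-subject prediction table.
Significance uses a permutation test: subjects' outcome records (slope,
visit days, trajectory) are reshuffled jointly n_perm times (default 1000),
the LOOCV prediction is rerun with the edge set held fixed, and
p = (1 + #{|r_null| ≥ |r_obs|})/(n_perm + 1), two-sided on |r| (one-sided by
flag); the add-one rule means p is never 0 and bottoms out at 1/(n_perm+1).
Re-selecting edges inside each permutation is available behind the same
interface (pass no precomputed selection per permutation) but is not the
default: the test targets the regression given the features, and the frozen
variant keeps 1000 permutations at interactive cost.

### Group classification

A subject is SBPr when the actual VAS decrease from baseline is at least
20% by visit four ("at least", i.e. ≥, with a strict-inequality flag because
the boundary convention is genuinely ambiguous in the literature). For
visits two and three the criterion rescales in proportion to the cohort's
mean drop: threshold_n = 20% × mean(VAS₁ − VASₙ)/mean(VAS₁ − VAS₄). The
published rescalings, 13% (visit 2) and 15% (visit 3), ship as defaults;
`recovery_thresholds="auto"` recomputes them from the data at hand.

Classification from the model scores each subject by the predicted ΔVAS₁ₙ.
AUC uses the rank (Mann–Whitney) formulation with ties counted ½, computed
on −ΔVAS so AUC > 0.5 means predicted recovery tracks actual recovery.
Accuracy, sensitivity and specificity are evaluated at a *fixed* operating
point — a subject is called SBPr when the predicted percent decrease meets
the visit's threshold — not at the ROC-optimal cut; a fixed cut is the
prospectively usable rule and explains why sensitivity can be 0 with
specificity 1 at early visits when predicted changes are uniformly small.
SBPr is the positive class.

### Seed baseline

The comparison model classifies SBPp/SBPr from a single baseline connection
between two spherical ROIs (published centres mPFC (2, 52, −2) and
NAc (10, 12, −8) in MNI mm). A sphere includes every voxel whose mm-space
centre lies within the radius of the centre (voxel-centre convention, no
partial-volume weighting). Radii 5, 6 and 10 mm are all first-class because
the original description left "10 mm" ambiguous between radius and diameter.
ROI mean time series are correlated (Pearson, plus Fisher z) and the single
value's AUC is reported in both orientations. On synthetic grids ROI centres
come from configuration; MNI coordinates apply to real-data runs only.

## Synthetic study design

The generator emulates the study's design: 49 subjects, 240 retained volumes
(244 acquired minus 4 dummies) at TR 2.5 s, VAS in [0, 100] with baseline
eligibility VAS > 40, four visits at 0 / 6.90±2.14 / 27.92±3.69 / 54.68±3.83
weeks (converted at 7 days/week, rounded, forced strictly increasing), and a
49% female share.

* **Spatial sources** are K non-overlapping Gaussian blobs on a small grid
  (default 12×12×10, K = 12). The mechanism is scale-free, so the desk-scale
  K stands in for the ~70-component order used on full-resolution data.
* **Component time courses** are i.i.d. multivariate normal across time with
  covariance equal to the inverse of a chain (tridiagonal) precision matrix,
  plus small per-subject jitter (SD 0.05). Because sampling is i.i.d., the
  true partial correlation is exactly −Q_ij/√(Q_ii Q_jj) of the precision Q —
  a closed-form oracle for the connectivity stage. No hemodynamics,
  autocorrelation, motion or drift are modelled.
* **Volumes** are maps × time courses plus white voxel noise (SD 0.5).
* **Outcomes**: each subject's slope is planted_weights · z_edges +
  N(0, noise_sd), with three planted edges of weight ±1 (VAS/day per z-unit)
  and noise_sd = 0.01 VAS/day — at T = 240 the between-subject edge SD of
  ~0.065 z gives slope spreads of ~0.09 VAS/day, i.e. changes of tens of VAS
  points over the ~55-week follow-up. Planted edges are drawn only from
  conditionally independent (non-adjacent) pairs of the chain, whose edges
  fluctuate around zero; planting on coupled pairs would shift every
  subject's slope by the large common mean and clamp most trajectories at
  the VAS bounds. Visit-2/3 scores get small jitter (SD 1 VAS); subjects
  whose trajectory hits 0 or 100 are clamped and flagged so exactness tests
  can exclude them. Baseline VAS is Uniform(41, 100) — a stand-in, since
  only the > 40 eligibility rule constrains the real distribution.

What passing on this generator shows: the estimators agree with their
closed-form/brute-force oracles, the selection rule recovers a planted sparse
signal at the study's n and T and controls false selection under the null,
and the prediction/classification chain is exact in the noiseless limit.
What it cannot show: performance under hemodynamic confounds, autocorrelated
or motion-contaminated noise, registration error, or the real covariance
structure of clinical cohorts — real-data figures (e.g. published r and AUC
values) are expectations about a specific clinical dataset, not properties
this package can certify.

## Numerical choices and degenerate inputs

* Partial correlation enforces exact symmetry ((A + Aᵀ)/2) and errors on
  zero-variance columns (named) and singular C + ρI (advises ρ > 0).
* Fisher z errors outside |r| < 1; ROI correlations of ±1 are nudged inside
  the domain by 1e−15 before transforming.
* LOOCV prediction errors when the design is rank-deficient overall or in
  any fold (leverage ≈ 1), naming the problem.
* LassoCV's duality-gap warnings at the small end of the path on near-exact
  fits are suppressed; they do not affect support recovery at the chosen
  penalty (tol 1e−4, max_iter 20 000).
* Empty atlas regions yield ratio NaN, "not involved", with a warning.
* The sphere mask errors when the centre is outside the volume's bounding
  box or no voxel centre falls inside the radius.

## Problem sizes

Validation runs use the study-scale cohort (n = 49, T = 240, K = 12 →
E = 66, 3 planted edges) for selection/prediction properties, 20 replicate
cohorts for the null-selection and permutation-calibration studies
(200 permutations per replicate; 1000 for the strong-signal check), K = 4
six-subject mixtures for ICA recovery, and T = 200, N = 8 datasets for the
partial-correlation oracle. These sizes make every property measurable on a
single CPU in minutes while keeping n, T and the visit design at the study's
own values.

## Known limitations

* Group ICA is FastICA-based; no ICASSO-style stability resampling and no
  Bayesian model-order estimation (the component count is set explicitly).
* The LOOCV stability rule is honest about its own optimism only through the
  permutation test; no nested outer evaluation of the selection step.
* The generator's i.i.d. time courses make T-scaling optimistic relative to
  autocorrelated fMRI noise.
* Real-data mode consumes preprocessed, registered NIfTI volumes; no image
  preprocessing is included.
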