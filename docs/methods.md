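# Methods

## The estimators

`rbconn` quantifies voxel-level resting-state functional connectivity three
ways, all operating on the N × p matrix of standardized in-mask BOLD series
(N time points, p gray-matter voxels, typically p ≫ N).

**RBC (regularized brain connectivity).** Each voxel's series y_i is
regressed on all remaining voxels with a ridge penalty:

    min_β  Σ_t ( y_i(t) − β₀ − Σ_{j≠i} β_j y_j(t) )²  +  λ Σ_j β_j² ,

and connectivity is the multiple correlation Cor(ŷ_i, y_i) = √R². The
intercept β₀ sits outside the penalty and is handled exactly by centering.
The solver works in the dual (Gram) form: with K = Y Yᵀ (N × N),

    ŷ_i = K₋ᵢ (K₋ᵢ + λI)⁻¹ y_i ,   K₋ᵢ = K − y_i y_iᵀ ,

so one factorization of (K + λI) serves all p voxels through
Sherman–Morrison rank-one downdates; the map costs O(N³ + pN²) instead of
p separate p-dimensional solves. Because the ridge smoother is symmetric
positive semi-definite, Cor(ŷ_i, y_i) ≥ 0: raw maps live in [0, 1]. The
equality of the dual solution with the primal closed form is enforced by
tests against an independent primal solver on N > p instances (tolerance
1e-8).

**GBC (weighted global brain connectivity).** The mean absolute Pearson
correlation of each voxel with every other in-mask voxel — a bivariate
average, blind to structure that leaves the mean |r| unchanged.

**NRC (non-redundant connectivity).** A supervised principal-component
regression per target voxel: screen predictors by absolute marginal
correlation (default: top 5% fraction; an absolute threshold θ is also
supported), extract principal components of the screened block, OLS of the
target on the first m components (default m = 3), connectivity =
Cor(fitted, observed). The screening/component defaults are package
defaults, configurable through `NrcConfig`; voxels whose screen comes up
empty get 0 by convention.

All maps are Fisher-transformed (atanh) before group analysis, with values
clipped at 1 − 1e-12 so a correlation numerically equal to 1 (possible at
tiny λ) stays finite.

## The penalty λ

λ enters on the raw residual-sum-of-squares scale of the objective above
and must be held fixed across all voxels and subjects of an analysis —
values computed at different λ are not comparable. Cross-validation is
deliberately not provided: BOLD series are temporally dependent, so the
habitual CV machinery is invalid here; analyses instead report a grid,
default (0.5, 1, 5, 10, 50, 100, 500), with 50 as the single-λ default.
Packaged ridge solvers that normalize the loss by N (e.g. glmnet) reach the
same shrinkage at approximately λ/N on their scale.

A scaling fact governs where this grid is informative: with standardized
columns the bulk eigenvalues of K grow like p, and the ridge only does
useful work when λ is comparable to the spectrum it must shrink. At a few
hundred in-mask voxels the printed grid brackets the bulk of the spectrum;
at several thousand voxels the same numerical grid would barely shrink
anything and RBC saturates near 1. The simulation studies in this package
therefore run at ~200 in-mask voxels (6×6×6 grid), N = 256, where λ = 50
sits mid-spectrum — the same relative regime the penalty occupies in the
intended full-scale application. The full-scale scenario defaults
(12×12×12 grid, ~650 in-mask voxels, 20 subjects/group) remain available
for users who also rescale λ.

## Volume preparation

- **Masking / voxel order.** In-mask voxels are raveled in raster order, x
  fastest, then y, then z (0-based indices). Only axis-aligned
  scaling+translation affines are accepted; oblique grids are rejected.
- **Resampling.** Block-mean downsampling by an integer factor (the coarse
  analysis grid exists to cut computational cost, and block means preserve
  the spatial mean exactly). Trailing partial blocks average the available
  voxels; masks are downsampled by block majority (> 50% in-mask).
- **Band-pass.** A hard DFT mask on [0.02, 0.1] Hz (DC always removed).
  Chosen over an IIR design for exact idempotence and bin-by-bin
  testability; the analysis band is all that matters downstream.
- **Standardization.** Mean 0, sample variance 1 (divisor N − 1).
  Zero-variance voxels cannot be standardized; they are dropped from the
  matrix and recorded, never NaN-propagated.

Degenerate RBC fits (fitted series indistinguishable from floating-point
cancellation noise, i.e. fitted norm < 1e-8 × the cancellation scale of
K α − y(yᵀα)) are assigned 0 and logged. The criterion is relative, not an
absolute variance floor, because the smoother legitimately attenuates the
fitted amplitude by ~1/λ at large λ while the correlation stays
well-conditioned.

## Group inference

Voxel-wise general linear model on the Fisher-scale maps: map values and
the regressor of interest (group indicator or clinical score) are
residualized against the nuisance covariates (plus intercept), and the t
statistic of the regressor's slope is computed per voxel. With a two-level
regressor and no nuisance this reduces exactly to the pooled two-sample t.
Voxels undefined in any subject are excluded from inference. Groups need at
least 3 subjects each.

Family-wise error is controlled by the permutation distribution of the
maximum TFCE score:

- **TFCE.** TFCE(v) = Σ_{h = dh, 2dh, … ≤ stat(v)} e(h,v)^E · h^H · dh with
  e(h,v) the voxel count of the suprathreshold component containing v.
  Defaults E = 0.5, H = 2, 26-connectivity — the standard published
  defaults of the method. The step is dh = max(stat)/n_steps (n_steps
  defaults to 100), computed from the observed map and then held fixed
  across permutations so enhanced scores are comparable. Monte-Carlo
  calibration runs use n_steps = 25: permutation FWE control is exact for
  any TFCE parameterization, and the coarser grid quarters the cost.
- **Permutations.** With nuisance covariates the Freedman–Lane scheme is
  used: residuals from the nuisance-only model are permuted and the full
  statistic recomputed. Two-group designs without nuisance enumerate all
  C(n, n₁) distinct assignments when that count does not exceed n_perm
  (p-values then become exact and seed-independent); otherwise permutations
  are sampled with the mandatory seed. p-values use (1 + b)/(m + 1) so they
  are never zero, with floor 1/(m+1). A warning fires below 20 distinct
  permutations.
- **Two-sided contrasts** run the positive and negative directions as
  separate one-sided max-TFCE tests and Bonferroni-combine (×2), matching
  the practice of reporting reductions and increases separately.

## The synthetic cohort generator

Each subject's in-mask series is Σ_c w_{v,c} L_c(t) + e_v(t): unit-variance
band-limited Gaussian latents L_c shared within voxel communities
(spectral support 0.02–0.1 Hz), plus stationary AR(1) noise
e_v(t) = ρ e_v(t−1) + ε, ε ~ N(0, σ²). AR(1) noise (not white) keeps the
temporal dependence that invalidates cross-validation represented in every
test. Defaults emulate the intended acquisition regime: N = 256 volumes at
TR = 2 s on a coarse 4 mm-like grid; ρ = 0.3, σ = 1, community coupling
0.6 were chosen once as plausible resting-state values (lag-1
autocorrelation ≈ 0.3 and mid-range within-community correlations after
noise).

Closed forms used for validation: stationary noise variance
σ'² = σ²/(1 − ρ²); marginal voxel variance Σ w² + σ'²; correlation of two
voxels sharing one latent w_i w_j / √((w_i² + σ'²)(w_j² + σ'²)).

Group effects multiply patients' coupling to a latent by a factor g on a
voxel set; g = 1 makes the groups' generative laws identical — the basis of
the type-I-error calibration, since group labels are then exactly
exchangeable. Per-subject randomness derives from the cohort seed by a
counter scheme (`default_rng([seed, subject_index])`), so cohorts
regenerate bit for bit.

**The multivariate-only scenario.** A block of voxels couples to one
block-wide latent (variance share s = 0.5), one latent per block half
(h = 0.1), and a private per-voxel latent (the remainder). Patients
reallocate coupling: the block-wide share drops to s' = 0.2 and the
half-block share rises to the value h' solved from

    (k/2 − 1)(s + h) + (k/2) s  =  (k/2 − 1)(s' + h') + (k/2) s' ,

which preserves every voxel's mean absolute within-block correlation
exactly, while private shares keep the marginal variance at 1. Correlations
to out-of-block voxels are 0 in both groups. A bivariate-average measure
(GBC) therefore sees no systematic change anywhere, while the variance of a
block voxel predictable from the *other* voxels moves from s + h = 0.6 to
s' + h' ≈ 0.92 — visible at full strength to a multivariate estimator. This
is the regime behind the power-ordering comparison (RBC vs GBC significant
voxel counts). An earlier, simpler design (swapping shared against private
coupling) was rejected: it moves within-block |r| so much that the
bivariate average detects it too.

## What the simulations do and do not show

The generator produces stationary Gaussian community-structured signal with
AR(1) noise. It does not emulate hemodynamic convolution, motion or
physiological artifacts, scanner drift, spatial noise correlations, or
non-stationarity. Passing calibration here shows the inference machinery is
correct under exchangeability; it does not certify behavior under realistic
artifact structure, which upstream preprocessing is assumed to have
handled.

## Monte-Carlo problem sizes

- FWE calibration: 200 null cohorts, 6×6×6 grid (216 voxels), N = 256,
  10 subjects/group, 200 permutations, TFCE n_steps = 25, α = 0.05.
- Power ordering: 50 cohorts of the multivariate-only scenario at the same
  sizes; RBC at λ = 50 vs GBC, two-sided FWE 0.05.
- Generator fidelity: 3-voxel community, heterogeneous weights
  (1.0, 0.7, 1.3), ρ = 0.3, N = 4096, tolerance ±0.05.
- Ridge dual/primal agreement: 100 random instances, N ∈ [12, 30),
  p ∈ [3, 10), λ ∈ (0.1, 200), tolerance 1e-8.

## Known limitations

- The premorbid-IQ pooled t computed from rounded summary statistics
  (means 23.14 vs 23.12, SDs 4.34 vs 4.49, n = 74/74) is −0.028; a
  demographics table built from the unrounded data can print −0.02. The
  package reports the formula value.
- TFCE uses a discrete threshold sum, not the continuous integral; results
  depend (weakly) on n_steps, and the observed-map-derived dh makes
  enhanced scores comparable within, not across, analyses.
- NRC's screening threshold and component count are package defaults, not
  values with an external provenance.
- Exhaustive enumeration is implemented for two-group designs without
  nuisance; Freedman–Lane with nuisance always samples (its permutation
  space is n!).
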