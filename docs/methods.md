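# Methods

This note records the models, numerical choices, and design decisions behind
`connectograd`, and what the synthetic validation does and does not
demonstrate.

## Connectopic mapping

**Fingerprints.** ROI and target voxel series are z-scored per voxel; the
target matrix (T × V_t) is decomposed by SVD and each ROI voxel is correlated
with the retained temporal components, scaled by the singular values.
Components are kept until their cumulative squared-singular-value fraction
reaches `variance_kept` (default 1.0, capped at numerical rank, so the
default compression is lossless). Because the compression is an orthogonal
rotation of the raw (per-target-voxel) correlation fingerprints, pairwise
Euclidean geometry is preserved exactly; the grand-mean term of the
eta-squared formula is *not* rotation-invariant, so the `Fingerprints` object
also carries each row's raw-space mean, computed exactly from the target mean
series without materializing the raw matrix. The similarity matrix computed
from the compressed object therefore equals the raw-fingerprint similarity to
machine precision at full retention (verified against a brute-force oracle);
with `variance_kept < 1` only the distance term is approximated.

**Eta-squared.** Implemented exactly as stated in the README; degenerate
denominators (both vectors constant and equal to the grand mean) return 1
when the vectors are identical and raise otherwise. The matrix form expands
‖a−b‖² via inner products; agreement with the direct scalar formula is
limited by cancellation to ~1e−8 on adversarial inputs.

**Graph.** Symmetric-union kNN on eta-squared with default k = 8, keeping the
similarity as edge weight; if the graph is disconnected, k is incremented
until it connects (logged). A dense mode (full off-diagonal similarity) is
available as a config fallback. The kNN rule is a documented stand-in: the
method's sources say only that the similarity matrix is transformed into a
connected graph.

**Eigenmaps.** The generalized problem L v = λ D v is solved in
symmetric-normalized form (D^−1/2 L D^−1/2, then v = D^−1/2 u) with a dense
symmetric eigensolver — ROIs here are a few hundred to a few thousand voxels,
where dense is fast and deterministic. The trivial λ = 0 eigenvector is
discarded; an error is raised if λ₂ ≈ 0 (effective disconnection);
(near-)degenerate eigenvalue gaps are logged as non-unique gradients. Each
gradient is min-max normalized to [0, 1]. Sign convention: eigenvector sign
is arbitrary, so the dominant gradient is oriented against a reference
gradient when one is given, else so that it increases with the world
z-coordinate (inferior → superior); `align_sign` flips via value → 1 − value.
Group gradients are voxelwise means of sign-aligned maps (aligned to the
running mean), renormalized.

## Trend-surface model

Coordinates handed to the TSM are world (mm) coordinates from the NIfTI
affine, z-scored per axis before powering — the sources are silent on
scaling; standardization keeps the cubic design well-conditioned and makes
coefficients comparable across subjects sharing a mask (and leaves the
rank-based cohort statistics invariant in any case). The basis has no cross
terms: x, y, z, x², y², z², x³, y³, z³ at order 3 — nine reported
coefficients; the intercept is fit but not reported. Degenerate axes (planar
masks) have their columns zeroed and flagged.

"Bayesian linear regression" is implemented as the standard parameter-free
choice: a zero-mean isotropic Gaussian coefficient prior with prior and noise
precisions (α, β) set by evidence maximization (MacKay fixed-point updates on
the eigenbasis of XᵀX; init α = 1e−6, β = 1/var(y); tolerance 1e−8, ≤ 300
iterations). The returned log-evidence is tested against a grid search, and
the whole fit against an independent evidence-maximized ridge implementation.
`var_explained` = 1 − RSS/TSS of the gradient values. Fitting each order
independently makes the per-order variance profile non-decreasing in practice
but not by construction; the shrinkage is data-driven per order.

## Quality control

Two inclusion rules, both pure functions of their inputs: the TSM must
explain at least 70% of the gradient's spatial variance (inclusive bound:
exactly 0.70 passes), and |Pearson r| between the subject's dominant gradient
and the reference must reach `r_min` (default 0.5 — the direction criterion
is qualitative in the method's sources; the correlation threshold is this
package's operationalization, and configurable). Excluded-vs-included
comparability uses Student's t (equal-variance; Welch by flag) for continuous
and Fisher's exact test for binary variables, uncorrected (descriptive).

## Cohort statistics

Partial Spearman is frozen to the rank-residual definition: rank-transform
x, y, covariates; residualize ranked x and y on ranked covariates (with
intercept) by least squares; ρ = Pearson of residuals; p from the t
approximation with df = n − 2 − #covariates. (The partial-correlation
recursion on the rank correlation matrix is algebraically identical and
serves as the independent test oracle.) "Controlling for" covariates in the
Mann-Whitney U is implemented as linear residualization of the values before
the rank test — the mechanism is not specified by the sources; an unadjusted
mode exists for comparison. The U null distribution is enumerated exactly
when both groups have ≤ 8 members, otherwise the normal approximation with
tie correction is used. FDR families are one per (outcome × test) across the
nine coefficients; q-values come from the Benjamini-Hochberg step-up rule
(statsmodels), tested against a hand-rolled oracle. All tests are two-sided;
sex enters as a 0/1 covariate; missing values are deleted listwise per
outcome. Conventional-connectivity baselines are mean Fisher-z of within-mask
pairwise correlations (intrinsic) or mask-to-target correlations
(whole-brain), with correlations clipped at 1 − 1e−7 before atanh and clips
logged.

## Synthetic data

The generator plants everything downstream stages estimate.

* **Network signals**: band-limited Gaussian noise (moving-average window 5),
  whitened in-sample so the K signals are exactly uncorrelated, unit
  variance. Not HRF-convolved — resting-state-like correlation structure is
  all the pipeline consumes.
* **Planted gradient**: ROI voxels at normalized position s along the
  gradient axis mix the network signals with weights w(s); the default axis
  is (0.2, 0.3, 1)/‖·‖ — mostly inferior→superior but slightly oblique.
  A grid-aligned axis on a small ROI quantizes s into as few distinct values
  as the ROI has planes (8 on an 8×8×8 ROI), a degenerate geometry that
  fragments the kNN graph into plane-cliques and collapses the Fiedler vector
  to a two-cluster step; real cortical gradients are not grid-aligned. The
  default scenario is an 8×8×8 ROI (2 mm voxels), T = 300, K = 2 networks of
  100 target voxels each on a disjoint grid, voxel noise at 0.5 of signal sd.
* **Mixing profiles**: "linear" w₂(s) = s (constant stepwise change, the
  healthy layout) and "clustered" w₂(s) = s^γ with curvature exponent γ > 1 —
  a large uniform inferior portion with change compressed toward the superior
  end. Under a cubic TSM the mapping γ → coefficients is strictly monotone
  over γ ∈ [1.8, 4.2]: first-order z falls, z² and z³ rise. A symmetric
  logistic steepness knob was evaluated and rejected: it *raises* the
  first-order coefficient (a centered step has a large linear component) and
  drives z³ negative — the opposite of the clustered-organization coefficient
  pattern this generator is meant to emulate.
* **Artifact subjects**: focal signal loss plus outliers — the ROI's network
  coupling is attenuated (×0.15, replaced by matching-amplitude fresh noise)
  and `n_outliers` voxels are replaced by independent high-amplitude noise
  (amplitude 5). Both constants were calibrated once and frozen
  (variance-gate failure in ~100% of seeds, clean subjects pass in 100%).
  Outliers alone cannot produce an artifactual dominant eigenmap: under
  L v = λ D v the normalized cut isolating a small voxel group is O(0.1–1)
  while an intact smooth gradient chain sits at ~1e−3, so the gradient always
  wins; artifactual eigenmaps arise when the gradient signal itself is gone,
  which is what the attenuation models. With `n_outliers = 0` the subject is
  returned clean and bit-identical to the standard generator.
* **Cohorts**: each subject carries a latent standardized log-curvature z;
  γ = exp(log 2.9 + 0.12·(z + 0.8·carrier)), the range over which the
  coefficient mapping is monotone. Outcome columns (p-tau, t-tau, immediate
  memory) are generated with stated latent correlations (defaults +0.5,
  +0.45, −0.35) and dressed with realistic location/scale (e.g. p-tau
  48.4 ± 18.1 pg/ml, age 63.3 ± 5.0 y, education 15.5 ± 3.4 y, 70% female,
  38% ε4 carriers); covariates are independent of the planted effects so the
  adjusted tests calibrate cleanly. Each subject's *gradient map* is the
  clustered profile on the ROI grid along the pure z axis (the direction the
  dominant gradient runs; no eigenmap is involved in the fast path, so axis
  alignment is harmless and keeps x/y coefficients as true nulls) plus voxel
  noise at 0.05 — matching the empirical jitter of the full pipeline, whose
  recovered gradients correlate ≈ 0.998 with the planted positions. TSM
  coefficients in the cohort table are produced by the real trend-surface
  fit, subject by subject.

### What the synthetic validation shows — and does not

Passing tests demonstrate that the estimator chain is internally correct
(oracle equivalences at machine precision), that it recovers a planted
spatially continuous gradient under substantial voxel noise, that the
variance gate separates intact from signal-lost subjects, and that the
statistics stage is calibrated (family-wise discovery ≤ 5% under the null)
and powered (≥ 97% with the planted sign pattern at latent r = 0.5,
n = 100). They do not demonstrate performance on real fMRI: the generator has
no hemodynamics, motion, physiological noise, spatial autocorrelation, or
registration error, its networks are exactly two orthogonal signals, and its
artifact model is one specific failure mode. Cohort effect sizes in real data
are not reproduced here — the generator's couplings are structural stand-ins,
not estimates.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeds carried in the
scenario objects; every generator is bit-reproducible under its seed. The
validation suite uses the scales at which the properties are stated: 20-seed
recovery sweeps, 50-seed QC rates, 200-replicate null/power calibrations at
n = 100 subjects, dense-eigensolver oracles up to 200 nodes. The full test
suite runs in about a minute on one CPU; `scripts/acceptance.py` in about
half a minute.

## Known limitations

* The kNN graph rule and the direction-criterion threshold are documented
  stand-ins for under-specified steps of the original method.
* Gradients are volumetric only (no surface/vertex support); one gradient
  axis is planted and only the dominant eigenmap is validated against truth.
* The evidence-maximized ridge assumes i.i.d. residuals; spatial
  autocorrelation of real gradient maps will make `var_explained` optimistic
  relative to an autocorrelation-aware model.
* Whether HCP-like and cohort-like analyses share voxel orderings/resampling
  is irrelevant for synthetic grids but untested for real data with differing
  affines.
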