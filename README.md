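# connectograd

Connectopic mapping of functional-connectivity gradients, with trend-surface
parameterization, subject-level quality control, and covariate-adjusted
nonparametric cohort statistics — plus a synthetic-data generator that plants
known gradients and couplings so the whole chain can be validated end to end.

## The problem

Classical parcellations split a cortical region such as the medial parietal
cortex (precuneus, posterior cingulate, retrosplenial cortex) into discrete
subregions, but its functional connectivity in fact changes *continuously*
across space. Connectopic mapping represents this organization as smooth
**connectivity gradients**: per-voxel scalars that vary continuously where
connectivity profiles vary continuously. Summarizing each subject's dominant
gradient with a handful of spatial-polynomial coefficients turns individual
functional organization into quantities that can be correlated with
biomarkers (e.g. CSF tau species), genotype (e.g. ApoE ε4 carriership), and
cognition across a cohort — a candidate marker for early, subtle
reorganization in populations at risk of Alzheimer's disease.

## The method

Given a masked 4D BOLD acquisition, an ROI mask, and a target (whole-brain)
mask:

1. **Fingerprints.** Each ROI voxel's *connectivity fingerprint* is its vector
   of Pearson correlations with the target voxel time series, computed in an
   SVD-compressed basis: the fingerprint entries are correlations with the
   retained temporal components *u_c*, scaled by the singular values *s_c*.
   At the default retention (all variance, up to numerical rank) the
   compression is lossless for the similarity computation.
2. **Similarity.** Fingerprints *a, b* are compared with the eta-squared
   measure

   η² = 1 − Σᵢ[(aᵢ−mᵢ)² + (bᵢ−mᵢ)²] / Σᵢ[(aᵢ−M)² + (bᵢ−M)²],

   mᵢ = (aᵢ+bᵢ)/2, M = mean of all elements of a and b; η² ∈ [0, 1].
3. **Graph + eigenmaps.** The similarity matrix is sparsified to a connected
   symmetric k-nearest-neighbor graph (k auto-escalates if disconnected) and
   decomposed by Laplacian eigenmaps: solve L v = λ D v with L = D − W. The
   eigenvector of the smallest nonzero λ, min-max normalized to [0, 1], is the
   **dominant gradient**.
4. **Trend-surface model (TSM).** The gradient map g(x, y, z) is regressed on
   per-axis monomials of the standardized world coordinates — x, y, z, x², y²,
   z², x³, y³, z³ at order 3, i.e. **nine spatial coefficients** (plus an
   internal intercept) — by Bayesian linear regression with a zero-mean
   isotropic prior, both precisions set by evidence maximization (type-II ML).
   First-order coefficients capture the slope of connectivity change along
   each axis; higher orders capture curvature/clustering.
5. **QC.** A subject enters cohort statistics only if the TSM explains ≥ 70%
   of the gradient's spatial variance and the gradient preserves the main
   direction of the reference (group) gradient (|r| ≥ 0.5 by default).
   Excluded-vs-included comparability is reported with t/Fisher tests.
6. **Cohort statistics.** Per TSM coefficient: partial Spearman rank
   correlations with continuous outcomes (rank-residual definition) or
   Mann-Whitney U-tests on covariate-residualized values for group contrasts,
   controlling for age, sex (and education), with Benjamini-Hochberg FDR
   within each outcome family. Conventional scalar connectivity (mean
   Fisher-z within/whole-brain) is available as a baseline.

## Worked example

```python
import numpy as np
from connectograd import (GradientScenario, simulate_gradient_bold,
                          connectopic_gradients, make_basis, fit_tsm,
                          check_variance)
from scipy.stats import spearmanr

sc = GradientScenario(seed=0)           # 8x8x8 ROI, T=300, noise_sd=0.5
roi, target, truth = simulate_gradient_bold(sc)
grads, info = connectopic_gradients(roi, target)
g = grads[0]
print(f"dominant gradient: eigenvalue={g.eigenvalue:.4f}, k_used={info['k_used']}")
print(f"recovery |Spearman| vs planted positions: "
      f"{abs(spearmanr(g.values, truth).statistic):.3f}")

basis = make_basis(roi.coords_world(), order=3)
model = fit_tsm(g, basis)
print(f"var_explained={model.var_explained:.3f} -> "
      f"QC {'pass' if check_variance(model) else 'fail'}")
```

prints

```
dominant gradient: eigenvalue=0.0003, k_used=8
recovery |Spearman| vs planted positions: 0.998
var_explained=0.981 -> QC pass
```

The generator plants a gradient along a mostly inferior→superior axis; the
recovered dominant eigenmap tracks the planted voxel positions at
|Spearman| ≈ 0.998, and the order-3 TSM describes 98% of its spatial
variance — the first-order z coefficient (+0.387 here) dominates, as expected
for a constant stepwise change along z.

The same steps are available as a CLI:

```bash
connectograd simulate --out sim --seed 0
connectograd gradient --bold sim/roi_bold.nii.gz --roi sim/roi_mask.nii.gz \
    --target sim/target_bold.nii.gz --out grad/s0
connectograd tsm --gradient grad/s0_gradient1.nii.gz \
    --roi sim/roi_mask.nii.gz --subject S0 --out coeffs.tsv
connectograd qc --coeffs coeffs.tsv --out qc
connectograd simulate --mode cohort --out cohort --seed 0
connectograd stats --cohort cohort/cohort.tsv --spec spec.json --out stats.tsv
```

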