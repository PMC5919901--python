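# Methods

This note records the models, numerical choices and study conditions behind
`paleobrain`, and what the phantom-based validation does and does not show.

## Spatial conventions

Voxel indices are 0-based; world coordinates are `affine · (i, j, k, 1)` in
mm, RAS+. The +x axis (array axis 0) is the left–right axis; midsagittal
flips are reversals of axis 0 about the grid centre plane (for even
dimensions, the half-voxel plane between the two middle slices, so
`labels[::-1]` realizes the flip exactly). Scalar images are interpolated
trilinearly with edge clamping; label images by nearest neighbour with
background (0) outside the grid. Meshes are stored as binary
little-endian PLY (exact float round-trip); landmarks and tables as CSV.

## Deformation model

A deformation is the group exponential of a stationary velocity field `v`
(voxel displacement per unit flow time), computed by scaling and squaring
with `N = 6` steps. Deformations use the pull-back convention throughout:
`phi[x]` is the source coordinate sampled at fixed-grid voxel `x`, so
`warp(I, phi)(x) = I(phi(x))` and `compose(a, b)(x) = a(b(x))`. The inverse
of `exp(v)` is `exp(−v)`; on the smooth fields used here the two compose to
identity within a few hundredths of a voxel, and the Jacobian determinant
of `exp(v)` stays positive at interior voxels. Against a 256-step
forward-Euler flow oracle the `N = 6` exponential agrees to well under
0.02 voxels for fields with ‖v‖∞ = 1.5 on a 16³ grid smoothed with a
σ = 4 voxel Gaussian; the error decreases monotonically in `N`.

## Registration

The objective is

    E(v) = Σₓ (M(exp(v)(x)) − F(x))² + λ [ μ Σᵢⱼ eᵢⱼ(v)² + (λₗ/2) Σ (div v)² ]

with strain `eᵢⱼ = (∂ᵢvⱼ + ∂ⱼvᵢ)/2` discretized by central differences with
replicated boundaries. Defaults: `λ = 0.01`, `μ = 1`, `λₗ = 0.5`, three
dyadic resolution levels with (40, 30, 20) iterations, step size 0.4 voxels.
The optimizer is steepest descent with step halving on the *exact* discrete
objective, so the accepted-objective trace is non-increasing by
construction. The descent direction is the first-order (small-deformation)
data gradient `2 (M∘φ − F) ∇(M∘φ)` plus the elastic gradient
`−μ(Δvⱼ + ∂ⱼ div v) − λₗ ∂ⱼ div v`, preconditioned by a σ = 1.5 voxel
Gaussian — a symmetric positive semi-definite operator, so preconditioning
preserves the descent property; any residual gradient/objective mismatch at
boundaries is absorbed by the step-halving acceptance test. Registration of
endocast shapes operates on binary masks smoothed with a 2-voxel-FWHM
Gaussian, since fossil "images" are masks.

Affine pre-alignment is moment-based: centroids, principal inertia axes
(sign-fixed, reflection-free) and the isotropic scale `∛(volume ratio)`;
near-degenerate inertia spectra fall back to centroid + scale. Volumes
measured after pre-alignment are restored to native scale with the affine
determinant.

Known-deformation self-recovery on the textured phantom (true fields with
‖v‖∞ = 2 voxels, σ = 8 voxel correlation length at 48³) recovers the
deformation to < 0.5 voxels mean inside the brain. Two caveats are
inherent, not implementation artifacts: inside homogeneous regions the
image term carries no information (aperture problem), so interior accuracy
rests on the elastic prior; and mask-driven endocast registration
constrains mainly the surface-normal component, so reconstruction accuracy
degrades gracefully as the generative warp gets rougher than the prior.

## Template and fossil reconstruction

The population template alternates (register all images to the current
template) with (template ← mean of warped images), a fixed number of outer
iterations (default 2–3); supplying paired brain images yields the
population-average brain through the same deformations. Fossil
reconstruction registers the (pre-aligned, smoothed) fossil endocast to the
average endocast, then pulls the average brain and the atlas labels into
the fossil frame through `exp(−v)` — the average brain rather than any
individual brain, so the estimate is free of subject-specific folding
idiosyncrasies; the single-subject mode exists only as an evaluation
control, where it is measurably worse. Parcel volumes use hard nearest
labels (voxel counts × voxel volume), gated to the reconstructed brain mask
dilated by one voxel. Pseudo-cohorts (every individual's template-space
warp composed with every fossil deformation) emulate within-fossil-group
variation.

## Endocast restoration

Interpolating 3-D thin-plate splines with the biharmonic kernel
`U(r) = r` (the correct 3-D choice; `r² log r` is 2-D). The warp maps every
source landmark exactly onto its target and reproduces affine maps with
zero bending energy; bending energy `Σ_d w_dᵀ K w_d` is invariant to rigid
motion of both configurations. Restoration fits the TPS from landmarks on
the damaged specimen to an intact reference (pull-back direction),
resamples the reference only inside the hole mask, and closes residual
≤ 2-voxel cavities morphologically. The optional second iteration adds
closest-point pseudo-landmarks near the holes and refits; semi-landmark
*sliding* is deliberately not implemented — correspondences are treated as
fixed, which the synthetic generator guarantees.

## Tissue segmentation

A three-class 1-D Gaussian mixture fit by EM inside a head mask, k-means++
initialized (deterministic per seed), classes reported in CSF < GM < WM
mean order regardless of initialization, with a variance floor for
degenerate (noise-free) data. The plain-EM log-likelihood trace is monotone
non-decreasing; the optional mean-field Potts term (`mrf_beta > 0`, default
off) couples neighbouring posteriors and is excluded from that guarantee.
Masks use the majority rule (brain = GM+WM ≥ 0.5, endocast =
GM+WM+CSF ≥ 0.5); ICV is the *soft* fraction sum × voxel volume, which
stays within a few percent of the thresholded count on phantoms.

## Surface morphometry

Homologous meshes come from pulling the template-surface vertices through
each specimen's inverse deformation (identical connectivity, vertex-wise
anatomical correspondence). Generalized Procrustes removes translation,
scale (unit centroid size — the size-normalization choice) and rotation
(SVD, reflections excluded), iterating the mean to 1e-10. Per vertex, the
two-sample Hotelling statistic on 3-D displacement vectors is
`T² = (n_a n_b/n) d̄ᵀ S⁻¹ d̄` with pooled covariance `S` (trace-scaled ridge
1e-8 when singular, as with 2+2 specimens), and parametric p from
`F = T²(n−4)/(3(n−2))`. Signed displacement maps project group-mean vertex
differences on area-weighted consensus normals. Family-wise error over
vertices is controlled by the permutation distribution of the maximum T²
(exact enumeration when the number of distinct labelings is small), which
is exact under group exchangeability; random-field-theory inference is a
non-goal. An omnibus Pillai-trace MANOVA map is provided as a secondary
route; pairwise contrasts are the default. Null simulations (20 replicates,
2×10 specimens, 500 permutations) keep the family-wise error at the nominal
0.05, and a 3 mm inserted bump is detected with ≥ 95 % far-field
specificity.

## Group statistics

* `volume_summary`: n−1 SDs; the cerebellum/cerebrum ratio is the mean of
  per-specimen ratios, not the ratio of means. Volumes are carried in mm³
  and reported in cc.
* ICV adjustment is two-step residualization (one pooled ICV slope,
  analysis on residual + grand mean), keeping the k-group ANOVA error df at
  N − k (1190 at N = 1193) rather than N − k − 1; adjusted values are
  exactly orthogonal to ICV and shift-invariant.
* Ryan's procedure: pairwise t with the pooled ANOVA MSE; a pair `r` ranks
  apart among `k` ordered means is tested at nominal level `2α/(k(r−1))`
  and declared significant only if all enclosing pairs are (step-down
  consistency). With k = 2 this is a plain two-sample t test. The exact
  schedule is isolated in `ryan_alpha` and configurable.
* Laterality: volumes from the symmetrized and mirrored atlas variants are
  averaged per region; simple main effects of side use within-specimen L−R
  differences against the pooled difference variance (df N − k, giving
  F₁,₁₁₉₀ at full cohort), while between-group contrasts per side run on
  the side-stacked table with error df 2N − 2k (t with df 2380). The
  symmetrized atlas itself comes from a template over originals ∪ x-flipped
  copies; its mirror swaps L/R region ids after flipping.
* Cognition regression: per task, `volume ~ intercept + score + ICV + age +
  sex` (df n − 5 = 1090 at n = 1095), Bonferroni over the 7 tasks. The
  reverse direction (`score ~ volume + confounds`) gives the identical t
  and p (partial correlation) and estimates the generative score-per-volume
  coefficient directly, which is what the recovery simulations check.

## Synthetic cohort: what it emulates, and what not

The canonical phantom is a deterministic, mirror-symmetric arrangement of
geometric parts (two cerebral ellipsoids, two cerebellar lobes, a vermis;
WM cores at 0.62 linear scale; a 2-voxel CSF shell defining the endocranial
cavity) on a 48³ unit-voxel grid, with a 25-region atlas in 13 lobe groups
and 14 named ray-cast surface landmarks. T1-like intensities are fixed at
CSF 0.2 / GM 0.6 / WM 1.0 plus Gaussian noise (default SD 0.03).

Each specimen is the canonical phantom warped by a single stationary
velocity: the sum of a group-effect field and an individual random field,
exponentiated once — so every specimen carries one invertible `true_warp`
and is topologically identical to the canonical phantom. Group volumetric
scale factors are realized as windowed radial contractions (linear scale
`f^{1/3}`, window = 1 inside the region with a σ = 2 voxel Gaussian decay
outside; regions sharing a factor are merged per connected component so
adjacent windows do not double-count). Individual variation is
white noise smoothed with an 8-voxel-FWHM Gaussian, boundary-tapered, and
scaled to a default 0.5 mm RMS displacement over the endocast — chosen once
so that regional volumes vary ~10 % between specimens, the order of real
between-subject variability. An optional `symmetrize` flag mirror-
symmetrizes every specimen's warp, giving exactly lateral-null cohorts for
testing.

Ground-truth regional volumes are voxel counts of the warped truth atlas;
at 48³ a sub-voxel boundary shift is only visible in cohort means through
dithering by individual variation, so a partial-volume-aware variant
(`soft=True`: trilinearly warped region indicators, summed) is provided for
sub-voxel effects such as the 0.9× lateral cerebellar deficit.

What the phantoms do **not** emulate: cortical folding, MRI bias fields and
artifacts, tissue-contrast variation, real endocast–brain decoupling
(phantom brains are deterministically nested in their endocasts), and
fossil taphonomy beyond spherical holes. Passing tests therefore
demonstrate the correctness and calibration of the machinery under the
stated generative model, not field performance on real scans; the published
dataset-scale numbers (e.g. millimetre-level surface deviations on 1,185
scans) have no phantom counterpart and are replaced by the analogous
ground-truth properties.

## Problem sizes and determinism

Default desk scales, fixed once: 48³ grids; 16³ for the Euler-oracle
comparison; leave-one-out benchmark with n = 8 and a lighter registration
schedule (15, 10, 6 iterations, one template pass); morphometry simulations
on 642-vertex icosphere meshes (the config documents the ~50,000-vertex
production scale) with 500 permutations and 20 null replicates; laterality
power at n = 20; full-cohort degrees-of-freedom checks at N = 1193 /
n = 1095 in table form only. All generators and analyses are pure functions
of their seeds; the CLI derives per-stage substreams from one master seed
by hashing, each below 2³¹.

## Known limitations

* Gauss–Newton (as in the reference flow-field method) is replaced by
  preconditioned steepest descent — simpler and adequate at these grid
  sizes, but slower to converge on large grids.
* Endocast-driven reconstruction cannot recover deformation components
  invisible to the cavity surface (deep fissure positions, tangential
  drift); accuracy claims are conditional on warp smoothness.
* The Ryan nominal-level schedule follows one published variant; authors
  differ, so it is isolated and configurable.
* Parcel accuracy offers both readings of the TP/TN-based "accuracy"
  ratio — the standard (TP+TN)/total is the default; the literal
  (TP+FN)/total variant is reported alongside as `literal_paper_formula`
  since the published formula appears internally inconsistent.
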