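# Methods

## Model

A point-distribution model treats each bone surface as an ordered list of
N corresponded 3-D vertices, stacked into a 3N-vector. After generalized
Procrustes alignment (rotation + translation, no scaling) of the M
training shapes, the model is

    x(b) = x̄ + Φ b,        b_i ~ N(0, λ_i),

with x̄ the arithmetic mean shape, Φ a 3N×K column-orthonormal matrix of
principal components of the centred data (SVD; eigenvalues use the 1/(M−1)
sample-covariance normalization; the sign of each mode is fixed so its
largest-magnitude coefficient is positive), and λ the per-mode variances
(mm²). Shape plausibility is the Mahalanobis distance
d(b) = √(Σ b_i²/λ_i). The model assumes the population is well described
by a low-dimensional linear subspace of corresponded coordinates — true by
construction for the synthetic cohorts here, approximate for real anatomy.

Mahalanobis distance is unbounded (it is a z-score norm); descriptions of
the fitting penalty as "ranging from 0 to 1" conflate the penalty *weight*
with the distance. This package uses the standard definition and a
separate penalty weight.

## Correspondence

Dense correspondence is established template-to-target:

1. **Anatomical frame.** Each bone (left bones mirrored about the
   medio-lateral axis first, with face winding flipped to keep volume
   positive) is expressed in a frame built from three named landmarks:
   origin at the base landmark, first axis toward the first head landmark,
   third axis along the landmark-plane normal, second completing the
   right-handed triad. The landmark recipe is configuration, not code:
   only approximate pre-alignment is needed downstream.
2. **Non-rigid warp.** The template is warped onto the target by a
   thin-plate-spline displacement field (scipy `RBFInterpolator`;
   Gaussian kernel optional) fitted to nearest-neighbour matches at a
   farthest-point subset of control points, iterated match → solve → warp.
   Three refinements matter in practice and are on by default in the study
   driver: a rigid ICP initialization (the landmark frame leaves residual
   pose), coarse-to-fine annealing of the smoothing weight (the field is
   nearly affine early and detailed late), and exact interpolation of the
   named landmarks as anchors. Anchoring exists because nearest-neighbour
   matching is blind to tangential motion: on an elongated shaft an axial
   shift between two bones produces almost no surface mismatch, so without
   anchors the warp converges to the wrong correspondence while fitting
   the surface perfectly.
3. **Rigid ICP.** Point-to-point ICP (closed-form Kabsch/SVD solve with a
   determinant guard so reflections are never returned) aligns the warped
   template to the target; its RMS nearest-neighbour residual is the
   per-shape registration error. The residual sequence is monotonically
   non-increasing.

The corresponded set is then Procrustes-aligned (4 iterations of
align-to-mean) before PCA. Without this step, per-subject frame wobble —
the landmarks that define each frame are themselves displaced by shape
variation and noise — injects rigid variance into the model and visibly
pollutes the spectrum.

## Fitting

Reconstruction minimises the quadratic objective

    F(T, b) = (1/n) Σ ‖T(x_i(b)) − y_i‖² + w Σ_j b_j²/λ_j

by alternating three closed-form steps: correspondence update
(nearest-neighbour match, full-surface mode only — landmark
correspondences are known by name), rigid solve (Kabsch), and a ridge
solve for b (diagonal in the full-surface case because Φ is orthonormal).
Each step cannot increase F, so the iteration terminates; the reported
trade-off J = data-RMSE + w·d(b) is logged alongside. With w = 0 a
training member is recovered exactly at full rank; as w → ∞ the fit
degenerates to a rigid alignment of the mean shape. No scaling degree of
freedom is fitted (an isotropic-scale flag exists but defaults off).

Full-surface fits select the number of modes as the smallest K whose
cumulative explained-variance ratio reaches 0.80 (re-selected per
cross-validation fold; a global override exists). Sparse fits use the
first three modes: three landmarks provide nine coordinate equations, and
after six rigid degrees of freedom three mode weights are the most that
remain uniquely determined. The talus is excluded from sparse fitting —
it has no externally accessible landmarks.

Key parameters (units, default, why):

| parameter | default | meaning |
|---|---|---|
| `penalty_weight` | 0.1 | Mahalanobis prior weight; balances data misfit (mm) against deformation plausibility |
| `variance_threshold` | 0.80 | explained-variance cut for full-surface mode count |
| `k` (sparse) | 3 | identifiable maximum for three landmarks |
| `n_control` | 200 (class) / all vertices (study driver) | TPS control points; at 642-vertex templates the full-rank solve is cheap and keeps fit RMSE ≪ noise |
| `regularization` | 1e-3 (class) / 1e-2 (study driver) | TPS smoothing; annealed from 1e4× down |
| `icp.max_iter`, `icp.tol` | 100, 1e-6 mm | standard point-to-point ICP stopping |
| `voxel_size` | 0.59 mm | Jaccard grid; echoes high-resolution MRI pixel spacing |

## Validation metrics

* **Jaccard index**: both watertight meshes are voxelized on one shared
  grid (voxel centre strictly inside the surface, half-open grid; the
  inside test is a z-ray parity rasterizer with a top-left fill rule on
  projected triangles, so a 10 mm cube at 1 mm voxels occupies exactly
  1000 voxels) and scored as |A∩B|/|A∪B|. Volumetric overlap is the
  definition; a nearest-neighbour point metric would not measure it.
* **Surface RMSE**: RMS of the pooled symmetric nearest-neighbour
  distances (A→B and B→A); directed variants are available.
* **Hausdorff**: symmetric maximum of the two directed worst-case
  distances, no percentile truncation. Always ≥ the RMSE of the same pair.

Leave-one-out cross-validation rebuilds the model without subject i, fits
the held-out subject (full surface or its landmark triple), and scores all
three metrics; mean (SD) per metric per fitting mode is reported with
two-sided Wilcoxon signed-rank p-values for the paired full-vs-sparse
differences (exact null for n ≤ 25 without ties; normal approximation with
tie correction otherwise; all-zero differences are reported as p = 1 and
flagged). Significance (0.05) is reported, never decided for the user.

## Synthetic cohorts

`footshape.synthetic` generates the test substrate: a deterministic
watertight template (elongated metatarsal-like solid with asymmetric
cross-section and dorsal bow; blocky calcaneus-like superellipsoid;
multi-lobed midfoot-like solid; ellipsoid), three named landmark vertices
at well-separated extremes, and smooth displacement modes built from
low-order polynomials of position directed along vertex normals,
orthogonalized against each other **and against the six-dimensional
rigid-motion subspace** (otherwise part of the nominal mode variance is
pose, which Procrustes alignment silently removes), then scaled to unit
RMS vertex displacement so a weight of b mm moves the surface b mm RMS.
Subjects are template + Σ b_j·mode_j + noise (along normals by default),
randomly posed, and mirrored for a configurable left fraction; everything
derives from one seed, bitwise reproducibly.

Default study conditions: 20 subjects, mode SDs (2, 1, 0.5) mm, 0.1 mm
noise, ±15° / ±20 mm poses, half left. What passing tests on this
substrate show — and do not show: the pipeline's correspondence, model
algebra, fitting and metrics are correct on smooth, closed,
single-component surfaces whose variation truly is low-rank and linear;
they do not certify accuracy on real segmentations with topological
noise, partial surfaces, segmentation bias, or non-linear anatomical
variation.

## Numerical choices and degenerate inputs

* Rigid transforms are validated (RᵀR = I, det R = +1, tolerance 1e-9);
  reflections are rejected — mirroring is an explicit separate operation.
* Volumetric operations refuse non-watertight meshes (reporting the open
  edge count) rather than repairing silently.
* Vertex welding on STL import is exact-match; STL stores float32, so a
  first read is exact only to float32, and every subsequent binary
  round-trip is bit-exact.
* Zero-variance modes: the Mahalanobis prior is undefined there; fits in
  the LOO harness truncate to the numerically positive modes, and a
  zero-variance population degrades to a rigid fit of the mean.
* Wilcoxon: exact method requires no zeros or tied absolute differences;
  the harness falls back to the corrected normal approximation.

## Known limitations

* **Mode-count selection vs. mode-SD profile.** With the default SD
  profile (2, 1, 0.5) mm the population variance ratios are 4 : 1 : 0.25,
  so ~95% of variance sits in two modes and the 0.80 threshold selects
  k = 2 — fewer modes than the 3 used by sparse fitting. Full-surface LOO
  accuracy is then limited by truncation of the 0.5 mm third mode
  (mean RMSE ≈ 0.6–0.7 mm rather than the ≈ 0.1 mm noise floor), and the
  usual expectation that full-surface fits dominate sparse fits can
  invert on the Jaccard metric. Real cohorts have long, slowly decaying
  spectra (seven–eight modes to reach 80%), where the threshold rule
  selects more modes than the sparse fit uses and the ordering is safe.
* **Subspace recovery scales with dimensionality.** Recovering the
  weakest generating mode from M samples in 3N dimensions requires iid
  vertex noise σ ≪ SD_min · √(M/3N); at M = 20, 3N ≈ 1900 the principal
  angle is ≈ √(3N/M)·σ/SD_min, so percent-level noise already costs
  several degrees.
* Sample SDs at M = 20 fluctuate with ≈ 16% standard error; any single
  cohort's spectrum (and hence its selected mode count) moves accordingly.
* Correspondence is template-biased (the first subject by default) and
  nearest-neighbour-driven; tangential sliding between anchors is
  unobservable and appears as extra apparent variance in trailing modes.
* Fitting assumes complete target surfaces; partial segmentations and
  image-intensity-based fitting are out of scope.
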