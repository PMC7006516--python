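# footshape

Statistical shape modelling of the functional foot segments — first
metatarsal, midfoot, calcaneus and talus — for biomechanists and
clinical-gait researchers who need personalised bone geometry without a
fresh MRI for every subject.

Given a training set of segmented bone surfaces (STL, millimetres), the
toolkit

1. mirrors left-side bones to right and pre-aligns every bone in an
   anatomical coordinate frame built from three named landmarks;
2. establishes dense correspondence by warping a template surface to each
   subject with a thin-plate-spline displacement field (optionally anchored
   on the landmarks) followed by rigid iterative-closest-point alignment;
3. Procrustes-aligns the corresponded set and builds a PCA
   point-distribution model: mean shape x̄, orthonormal modes
   Φ = [φ₁ … φ_K], eigenvalues λ₁ ≥ … ≥ λ_K, so any shape is
   `x(b) = x̄ + Φ b`;
4. reconstructs a new bone by fitting pose + mode weights to either a full
   surface or just **three** skin-accessible anatomical landmarks
   (TL/TM/TB on the first metatarsal, VMH/SMH/TN on the midfoot, PT/ST/CA
   on the calcaneus; the talus has no accessible landmarks and is excluded
   from sparse fitting), minimising the data misfit plus a Mahalanobis
   shape prior `w · √(Σ bᵢ²/λᵢ)` with default weight `w = 0.1`;
5. scores reconstructions in a leave-one-out cross-validation with the
   volumetric Jaccard index, symmetric surface RMSE (mm) and Hausdorff
   distance (mm), and compares full-surface against sparse-landmark
   accuracy with a paired two-sided Wilcoxon signed-rank test.

Because real MRI cohorts are rarely shareable, the package ships a
synthetic-data module that generates bone-like watertight surfaces from a
template deformed along known orthogonal shape modes, with surface noise,
random poses and left/right mirroring — the substrate for all tests.

## Worked example

Simulate a 10-subject cohort, build a model, then reconstruct one subject
from its full surface and from its three landmarks alone:

```bash
footshape simulate --n 10 --seed 42 --out-dir demo/pop
footshape build --dataset-dir demo/pop --out demo/model.npz --n-control 642
footshape fit --model demo/model.npz --target demo/pop/S04.stl --out demo/S04_full.stl
footshape fit --model demo/model.npz --landmarks demo/pop/S04_landmarks.xml --out demo/S04_sparse.stl
footshape metrics --a demo/pop/S04.stl --b demo/S04_full.stl
```

which prints

```
model: 10 shapes, 9 modes; mean registration RMSE 0.008 mm
explained variance: 0.631, 0.137, 0.101, 0.048, 0.031, 0.020, 0.015, 0.010, 0.008
fit (full): k=9, data RMSE 1.2389 mm, Mahalanobis 1.0083, J=1.3397
fit (sparse): k=3, data RMSE 0.1776 mm, Mahalanobis 1.4017, J=0.3177
jaccard   0.8046
rmse      1.3141 mm
hausdorff 3.1342 mm
```

Reading the numbers: the correspondence step fits each training surface to
well under the 0.1 mm simulated noise; the first three principal components
carry ~87% of the cohort's shape variance; the full-surface reconstruction
of S04 overlaps the ground-truth volume with Jaccard 0.80 and a mean
surface error of 1.3 mm. The sparse fit reproduces its three landmarks to
0.18 mm; its whole-surface accuracy is assessed the same way with
`footshape metrics`. `footshape validate` runs the complete leave-one-out
study and writes one record (subject, mode, Jaccard, RMSE, Hausdorff) per
row of a CSV.

The same pipeline is available as a library of scikit-learn-style
estimators — `PointDistributionModel`, `IterativeClosestPoint`,
`RBFRegistration`, `SurfaceFitter`, `LandmarkFitter` — with `fit`,
`transform`/`inverse_transform` and trailing-underscore fitted attributes;
see `docs/methods.md` for the model details and design choices.

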