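"""Correspondence via two-stage registration.

A dense correspondence across a training set is established by (1) warping
a template point cloud to each target with a radial-basis-function (RBF)
displacement field fitted to nearest-neighbour matches, then (2) rigidly
aligning the warped template to the target with iterative closest point
(ICP).  Because every warped cloud inherits the template's point count and
ordering, index i denotes the same anatomical location on all shapes —
the prerequisite for building a PCA point-distribution model.

Both registrations are exposed as scikit-learn style estimators with
``fit`` and trailing-underscore fitted attributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .geometry import GeometryError, PointCloud, RigidTransform

__all__ = [
    "IterativeClosestPoint",
    "RBFRegistration",
    "CorrespondedSet",
    "icp_register",
    "rbf_register",
    "build_correspondence",
    "farthest_point_indices",
    "kabsch",
]


def kabsch(source: np.ndarray, target: np.ndarray,
           weights: np.ndarray | None = None) -> RigidTransform:
    """Least-squares rigid transform mapping ``source`` onto ``target``
    (known correspondence), via SVD with a determinant sign guard so a
    proper rotation is always returned."""
    src = np.asarray(source, float)
    tgt = np.asarray(target, float)
    if weights is None:
        w = np.full(len(src), 1.0 / len(src))
    else:
        w = np.asarray(weights, float)
        w = w / w.sum()
    mu_s = w @ src
    mu_t = w @ tgt
    H = (src - mu_s).T @ ((tgt - mu_t) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_s
    return RigidTransform.from_rotation_translation(R, t)


def farthest_point_indices(points: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Greedy farthest-point subsample of ``points``; deterministic for a
    given seed (which selects only the starting point)."""
    pts = np.asarray(points, float)
    n = min(n, len(pts))
    rng = np.random.default_rng(seed)
    start = int(rng.integers(len(pts)))
    chosen = [start]
    d = np.linalg.norm(pts - pts[start], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    return np.array(chosen, dtype=np.int64)


class IterativeClosestPoint(BaseEstimator):
    """Classic point-to-point ICP rigid registration.

    Alternates nearest-neighbour matching with a closed-form (SVD/Kabsch)
    rigid solve.  The RMS residual is monotonically non-increasing across
    iterations.  Reflections in the closed-form solve are corrected by a
    determinant sign fix and never returned.

    Parameters
    ----------
    max_iter : maximum number of match/solve rounds.
    tol : stop when the residual improves by less than this (mm).

    Attributes
    ----------
    transform_ : recovered :class:`RigidTransform` (source -> target).
    residual_ : final RMS nearest-neighbour distance (mm).
    residual_history_ : residual after each iteration.
    n_iter_ : iterations actually run.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-6):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, source, target):
        src = source.points if isinstance(source, PointCloud) else np.asarray(source, float)
        tgt = target.points if isinstance(target, PointCloud) else np.asarray(target, float)
        tree = cKDTree(tgt)
        current = src.copy()
        T = RigidTransform.identity()
        history: list[float] = []
        prev = np.inf
        for _ in range(self.max_iter):
            d, idx = tree.query(current)
            step = kabsch(current, tgt[idx])
            current = step.apply(current)
            T = step.compose(T)
            d2, _ = tree.query(current)
            rms = float(np.sqrt(np.mean(d2**2)))
            history.append(rms)
            if prev - rms < self.tol:
                break
            prev = rms
        self.transform_ = T
        self.residual_ = history[-1] if history else 0.0
        self.residual_history_ = np.array(history)
        self.n_iter_ = len(history)
        return self


def icp_register(source, target, max_iter: int = 100,
                 tol: float = 1e-6) -> tuple[RigidTransform, float]:
    """Functional wrapper: return (transform, RMS residual in mm)."""
    icp = IterativeClosestPoint(max_iter=max_iter, tol=tol).fit(source, target)
    return icp.transform_, icp.residual_


class RBFRegistration(BaseEstimator):
    """Non-rigid registration of a template to a target via an RBF
    displacement field.

    Iterates: match each template point to its nearest target point, fit a
    smooth RBF displacement field (thin-plate spline by default) through a
    farthest-point subset of control points, warp, repeat — until the RMS
    nearest-neighbour distance stops improving.  The warped output has
    exactly the template's point count and ordering.

    Parameters
    ----------
    kernel : RBF kernel name (``scipy.interpolate.RBFInterpolator``);
        thin-plate spline by default, ``"gaussian"`` optional (epsilon set
        from the median control-point spacing).
    n_control : number of control points (farthest-point subsample).
    regularization : RBF smoothing weight.
    max_iter, tol : iteration control on the RMS residual (mm).
    step : fraction of the fitted displacement applied per iteration.
    seed : seed for the control-point subsample.

    Attributes
    ----------
    warped_ : warped template points, template ordering (N, 3).
    fit_rmse_ : RMS nearest-neighbour distance warped -> target (mm).
    rmse_history_ : residual per iteration.
    """

    def __init__(self, kernel: str = "thin_plate_spline", n_control: int = 200,
                 regularization: float = 1e-3, max_iter: int = 20,
                 tol: float = 1e-4, step: float = 1.0, seed: int = 0,
                 init: str = "icp", anneal: float = 1e4):
        self.kernel = kernel
        self.n_control = n_control
        self.regularization = regularization
        self.max_iter = max_iter
        self.tol = tol
        self.step = step
        self.seed = seed
        self.init = init
        self.anneal = anneal

    def _smoothing_at(self, iteration: int) -> float:
        """Coarse-to-fine anneal: smoothing decays geometrically from
        ``anneal * regularization`` to ``regularization`` over the run, so
        early iterations recover the global deformation and later ones the
        local detail."""
        if self.anneal <= 1 or self.max_iter <= 1:
            return self.regularization
        frac = iteration / (self.max_iter - 1)
        return self.regularization * self.anneal ** (1.0 - frac)

    def _solve_field(self, ctrl_pts, ctrl_disp, smoothing: float):
        kwargs = {}
        if self.kernel == "gaussian":
            tree = cKDTree(ctrl_pts)
            d, _ = tree.query(ctrl_pts, k=2)
            kwargs["epsilon"] = 1.0 / max(float(np.median(d[:, 1])), 1e-9)
        try:
            return RBFInterpolator(ctrl_pts, ctrl_disp, kernel=self.kernel,
                                   smoothing=smoothing, **kwargs)
        except np.linalg.LinAlgError as exc:
            # coincident control points make the kernel matrix singular
            uniq = np.unique(ctrl_pts, axis=0)
            dup = len(ctrl_pts) - len(uniq)
            raise GeometryError(
                f"singular RBF system ({dup} duplicate control point(s))"
            ) from exc

    def fit(self, template, target, anchors: dict[int, np.ndarray] | None = None):
        """Warp the template onto the target.

        ``anchors`` optionally maps template point indices to known target
        coordinates (e.g. named anatomical landmarks); the displacement
        field interpolates them exactly, pinning components of the
        deformation — such as sliding along an elongated shaft — that
        nearest-neighbour surface matching cannot observe.
        """
        tpl = template.points if isinstance(template, PointCloud) else np.asarray(template, float)
        tgt = target.points if isinstance(target, PointCloud) else np.asarray(target, float)
        if self.n_control > len(tpl):
            raise GeometryError(
                f"n_control={self.n_control} exceeds template size {len(tpl)}"
            )
        ctrl_idx = farthest_point_indices(tpl, self.n_control, seed=self.seed)
        anchor_idx = np.array(sorted(anchors), dtype=np.int64) if anchors else None
        if anchor_idx is not None:
            anchor_tgt = np.vstack([np.asarray(anchors[i], float) for i in anchor_idx])
            ctrl_idx = ctrl_idx[~np.isin(ctrl_idx, anchor_idx)]
        tree = cKDTree(tgt)
        current = tpl.copy()
        if self.init == "icp":
            # rigid initialization; the anatomical-frame pre-alignment
            # leaves a residual pose driven by landmark variability
            T0, _ = icp_register(current, tgt)
            current = T0.apply(current)
        elif self.init != "none":
            raise ValueError(f"init must be 'icp' or 'none', got {self.init!r}")
        best = current
        best_rmse = np.inf
        history: list[float] = []
        rising = 0
        for iteration in range(self.max_iter):
            d, idx = tree.query(current)
            rmse = float(np.sqrt(np.mean(d**2)))
            history.append(rmse)
            annealing = self._smoothing_at(iteration) > 2.0 * self.regularization
            if rmse < best_rmse - 1e-15:
                best, best_rmse = current.copy(), rmse
            if len(history) > 1 and rmse > history[-2] + 1e-15 and not annealing:
                rising += 1
                if rising >= 2:
                    warnings.warn(
                        "RBF registration diverging; returning best iterate",
                        RuntimeWarning, stacklevel=2,
                    )
                    break
            else:
                rising = 0
            if (not annealing and len(history) > 1
                    and abs(history[-2] - rmse) < self.tol):
                break
            disp = tgt[idx] - current
            smoothing = self._smoothing_at(iteration)
            if anchor_idx is None:
                interp = self._solve_field(current[ctrl_idx], disp[ctrl_idx],
                                           smoothing)
            else:
                # anchors interpolate exactly (zero smoothing) with the
                # full displacement; surface matches take partial steps
                pts = np.vstack([current[ctrl_idx], current[anchor_idx]])
                dsp = np.vstack([self.step * disp[ctrl_idx],
                                 anchor_tgt - current[anchor_idx]])
                smooth_vec = np.concatenate([
                    np.full(len(ctrl_idx), smoothing),
                    np.zeros(len(anchor_idx)),
                ])
                interp = self._solve_field(pts, dsp, smooth_vec)
                current = current + interp(current)
                continue
            current = current + self.step * interp(current)
        # final residual of the returned (best) iterate
        d, _ = tree.query(best)
        self.warped_ = best
        self.fit_rmse_ = float(np.sqrt(np.mean(d**2)))
        self.rmse_history_ = np.array(history)
        return self


def rbf_register(template, target, anchors: dict[int, np.ndarray] | None = None,
                 **kwargs) -> tuple[np.ndarray, float]:
    """Functional wrapper: return (warped template points, fit RMSE mm)."""
    reg = RBFRegistration(**kwargs).fit(template, target, anchors=anchors)
    return reg.warped_, reg.fit_rmse_


@dataclass
class CorrespondedSet:
    """A template plus M corresponded clouds, all with the template's point
    count and ordering, and the per-shape registration residual (mm)."""

    template: PointCloud
    shapes: np.ndarray  # (M, N, 3)
    fit_rmse: np.ndarray  # (M,)
    subject_ids: list[str] = field(default_factory=list)
    faces: np.ndarray | None = None  # template faces, if known

    def __post_init__(self):
        shp = np.asarray(self.shapes, float)
        if shp.ndim != 3 or shp.shape[2] != 3:
            raise GeometryError(f"shapes must be (M, N, 3), got {shp.shape}")
        if shp.shape[1] != len(self.template):
            raise GeometryError("corresponded shapes must match template size")
        rmse = np.asarray(self.fit_rmse, float)
        if rmse.shape != (shp.shape[0],) or (rmse < 0).any():
            raise GeometryError("fit_rmse must be one non-negative value per shape")
        if not self.subject_ids:
            self.subject_ids = [f"S{i:02d}" for i in range(shp.shape[0])]
        self.shapes = shp
        self.fit_rmse = rmse

    @property
    def n_shapes(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_points(self) -> int:
        return self.shapes.shape[1]

    def aligned(self, n_iter: int = 4) -> "CorrespondedSet":
        """Generalized Procrustes alignment (rotation + translation, no
        scaling): iteratively superimpose every shape on the evolving mean.
        Removes residual per-subject pose so PCA sees shape variation only.
        """
        shapes = self.shapes.copy()
        for _ in range(n_iter):
            mean = shapes.mean(axis=0)
            for i in range(shapes.shape[0]):
                shapes[i] = kabsch(shapes[i], mean).apply(shapes[i])
        return CorrespondedSet(
            template=self.template, shapes=shapes, fit_rmse=self.fit_rmse,
            subject_ids=list(self.subject_ids), faces=self.faces,
        )

    def drop(self, i: int) -> "CorrespondedSet":
        """Leave-one-out helper: the set without shape ``i``."""
        keep = [j for j in range(self.n_shapes) if j != i]
        return CorrespondedSet(
            template=self.template,
            shapes=self.shapes[keep],
            fit_rmse=self.fit_rmse[keep],
            subject_ids=[self.subject_ids[j] for j in keep],
            faces=self.faces,
        )


def build_correspondence(
    dataset: list[PointCloud],
    template_index: int = 0,
    faces: np.ndarray | None = None,
    subject_ids: list[str] | None = None,
    rbf_kwargs: dict | None = None,
    icp_kwargs: dict | None = None,
    order: str = "nonrigid_first",
    anchors: list[dict[int, np.ndarray] | None] | None = None,
) -> CorrespondedSet:
    """Register a template to every cloud in ``dataset``.

    All clouds must be the same segment, right-side (mirror lefts
    upstream), and pre-aligned in a common anatomical frame.  For each
    target the template is RBF-warped then rigidly ICP-aligned onto the
    target (``order="rigid_first"`` swaps the stages).  The template is
    included as its own zero-error correspondence.  ``anchors`` optionally
    supplies, per target, known landmark correspondences (template vertex
    index -> target coordinates) that the warp interpolates exactly.
    """
    if not dataset:
        raise GeometryError("empty dataset")
    sides = {c.side for c in dataset}
    if "left" in sides:
        raise GeometryError("left-side clouds must be mirrored before registration")
    if order not in ("nonrigid_first", "rigid_first"):
        raise ValueError(f"order must be nonrigid_first or rigid_first, got {order!r}")
    template = dataset[template_index]
    rbf_kwargs = dict(rbf_kwargs or {})
    icp_kwargs = dict(icp_kwargs or {})
    shapes = np.empty((len(dataset), len(template), 3))
    rmse = np.empty(len(dataset))
    errors: dict[int, Exception] = {}
    for i, tgt in enumerate(dataset):
        if i == template_index:
            shapes[i] = template.points
            rmse[i] = 0.0
            continue
        try:
            start = template.points
            anc = anchors[i] if anchors is not None else None
            if order == "rigid_first":
                T, _ = icp_register(start, tgt.points, **icp_kwargs)
                start = T.apply(start)
            warped, _ = rbf_register(start, tgt.points, anchors=anc, **rbf_kwargs)
            T, res = icp_register(warped, tgt.points, **icp_kwargs)
            shapes[i] = T.apply(warped)
            rmse[i] = res
        except Exception as exc:  # noqa: BLE001 - reported per shape
            errors[i] = exc
            shapes[i] = np.nan
            rmse[i] = np.nan
    if template_index in errors:
        raise GeometryError(f"template registration failed: {errors[template_index]}")
    if errors:
        failed = ", ".join(f"shape {i}: {e}" for i, e in errors.items())
        raise GeometryError(f"registration failed for some shapes ({failed})")
    ids = subject_ids or [f"S{i:02d}" for i in range(len(dataset))]
    return CorrespondedSet(template=template, shapes=shapes, fit_rmse=rmse,
                           subject_ids=ids, faces=faces)
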