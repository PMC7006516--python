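"""Reconstruct bone geometry by fitting a shape model to target data.

Two modes mirror clinical use:

* **full** — fit to a complete surface point cloud (e.g. an MRI
  segmentation): pose is initialized by ICP of the model mean onto the
  target, then nearest-neighbour correspondence, a closed-form rigid
  (Kabsch) solve and a ridge-penalized linear solve for the mode weights
  alternate to convergence.
* **sparse** — fit to three named anatomical landmarks only (the skin-
  accessible points used in gait labs): rigid Procrustes on the known
  landmark correspondences plus the same penalized weight solve, along the
  first three principal components (three landmarks give nine coordinate
  equations; after six rigid degrees of freedom, three modes are the most
  that remain uniquely determined).

The optimized objective is the quadratic surrogate

    F(T, b) = (1/n) sum_i ||T(x_i(b)) - y_i||^2 + w * sum_j b_j^2 / lambda_j,

non-increasing by construction across the alternating closed-form steps.
The reported trade-off ``J = data_rmse + w * mahalanobis(b)`` (the
Mahalanobis penalty weight ``w`` defaults to 0.1) is logged per iteration
so the data/prior balance is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .geometry import GeometryError, PointCloud, RigidTransform
from .io import LandmarkFile, LandmarkSchemaError
from .model import PointDistributionModel
from .registration import IterativeClosestPoint, kabsch

__all__ = [
    "FitResult",
    "SurfaceFitter",
    "LandmarkFitter",
    "UnsupportedSegmentError",
    "fit_full",
    "fit_sparse",
    "landmark_schemes",
    "DEFAULT_PENALTY_WEIGHT",
]

# penalty weight on the Mahalanobis shape prior (constrains deformation
# toward the training distribution)
DEFAULT_PENALTY_WEIGHT = 0.1


class UnsupportedSegmentError(ValueError):
    """Sparse fitting requested for a segment with no landmark scheme."""


_SCHEMES: dict[str, tuple[str, ...]] = {
    # most lateral / most medial projections of the head, most medial
    # projection of the base
    "first_metatarsal": ("TL", "TM", "TB"),
    # fifth-metatarsal head, second-metatarsal head, navicular tuberosity
    # (one triple from the six gait-lab midfoot labels; configurable)
    "midfoot": ("VMH", "SMH", "TN"),
    # peroneal tubercle, sustentaculum tali, upper central ridge of the
    # posterior surface
    "calcaneus": ("PT", "ST", "CA"),
    "synthetic": ("L1", "L2", "L3"),
}

MIDFOOT_LABELS = ("VMH", "SMH", "VMB", "SMB", "ID", "TN")


def landmark_schemes(segment: str | None = None,
                     override: dict[str, tuple[str, ...]] | None = None):
    """Built-in 3-landmark schemes per segment (user-overridable).

    The talus has no externally accessible anatomical landmarks and is
    excluded from sparse reconstruction.
    """
    schemes = dict(_SCHEMES)
    if override:
        for seg, names in override.items():
            if len(names) != 3:
                raise ValueError(f"scheme for {seg!r} must name exactly 3 landmarks")
            schemes[seg] = tuple(names)
    if segment is None:
        return schemes
    if segment == "talus":
        raise UnsupportedSegmentError(
            "the talus is excluded from sparse reconstruction: it has no "
            "externally accessible anatomical landmarks"
        )
    try:
        return schemes[segment]
    except KeyError:
        raise UnsupportedSegmentError(f"no landmark scheme for segment {segment!r}") from None


@dataclass
class FitResult:
    """Outcome of a shape-model fit.

    ``transform`` maps model space into target space; ``weights`` are the
    mode coefficients b; ``data_rmse`` is the RMS residual to the target
    data (mm); ``objective`` is J = data_rmse + penalty * mahalanobis.
    """

    transform: RigidTransform
    weights: np.ndarray
    mahalanobis: float
    data_rmse: float
    n_modes_used: int
    mode: str  # "full" | "sparse"
    reconstruction: PointCloud
    objective: float
    surrogate_history: np.ndarray = field(default_factory=lambda: np.zeros(0))
    converged: bool = True

    def __post_init__(self):
        if self.data_rmse < 0 or self.mahalanobis < 0:
            raise GeometryError("residuals must be non-negative")


def _solve_weights(modes_rows: np.ndarray, residual: np.ndarray,
                   eigenvalues: np.ndarray, penalty_weight: float,
                   n_points: int) -> np.ndarray:
    """Ridge solve for b: min (1/n)||A b - r||^2 + w sum b^2/lambda."""
    k = modes_rows.shape[1]
    A = modes_rows
    D = np.diag(penalty_weight * n_points / eigenvalues[:k])
    lhs = A.T @ A + D
    rhs = A.T @ residual
    return np.linalg.solve(lhs, rhs)


def _surrogate(sq_residual_mean: float, b, eigenvalues, w: float) -> float:
    return float(sq_residual_mean + w * np.sum(b**2 / eigenvalues[: len(b)]))


class _BaseFitter(BaseEstimator):
    def __init__(self, model: PointDistributionModel, k: int | None = None,
                 penalty_weight: float = DEFAULT_PENALTY_WEIGHT,
                 max_iter: int = 200, tol: float = 0.0):
        self.model = model
        self.k = k
        self.penalty_weight = penalty_weight
        self.max_iter = max_iter
        self.tol = tol

    def _resolve_k(self) -> int:
        model = self.model
        model._check_fitted()
        k = model.n_modes if self.k is None else int(self.k)
        if k > model.n_modes:
            raise GeometryError(
                f"k={k} modes requested but model has only {model.n_modes}"
            )
        if self.penalty_weight < 0:
            raise GeometryError("penalty_weight must be >= 0")
        return k

    def _finish(self, T, b, target_pts, mode, history, converged):
        model = self.model
        full = model.inverse_transform(b.reshape(1, -1))[0].reshape(-1, 3)
        recon = PointCloud(T.apply(full), label=model.segment_, side="right")
        d, _ = cKDTree(target_pts).query(recon.points) if mode == "full" else (None, None)
        if mode == "full":
            data_rmse = float(np.sqrt(np.mean(d**2)))
        else:
            lmk = recon.points[self._landmark_rows]
            data_rmse = float(np.sqrt(np.mean(np.sum((lmk - target_pts) ** 2, axis=1))))
        mah = model.mahalanobis(b)
        result = FitResult(
            transform=T, weights=b, mahalanobis=mah, data_rmse=data_rmse,
            n_modes_used=len(b), mode=mode, reconstruction=recon,
            objective=data_rmse + self.penalty_weight * mah,
            surrogate_history=np.array(history), converged=converged,
        )
        self.result_ = result
        self.transform_ = T
        self.weights_ = b
        self.reconstruction_ = recon
        return self


class SurfaceFitter(_BaseFitter):
    """Fit a shape model to a full target surface (point cloud or mesh
    vertices) by alternating nearest-neighbour correspondence, closed-form
    rigid alignment and a penalized linear solve for the mode weights.

    Parameters
    ----------
    model : fitted :class:`PointDistributionModel`.
    k : number of modes to deform along (default: all).
    penalty_weight : weight on the Mahalanobis shape prior (default 0.1).
    max_iter, tol : stop when the surrogate objective improves by < tol.

    Attributes
    ----------
    result_ : :class:`FitResult`; also unpacked as ``transform_``,
        ``weights_``, ``reconstruction_``.
    """

    def fit(self, target, y=None):
        model = self.model
        k = self._resolve_k()
        tgt = target.points if isinstance(target, PointCloud) else np.asarray(target, float)
        mean_pts = model.mean_.reshape(-1, 3)
        n = len(mean_pts)
        lam = model.eigenvalues_
        Phi = model.components_[:k].T  # (3N, k)
        w = self.penalty_weight

        # initial pose: ICP of the model mean onto the target
        icp = IterativeClosestPoint().fit(mean_pts, tgt)
        T = icp.transform_
        b = np.zeros(k)
        tree = cKDTree(tgt)
        history: list[float] = []
        prev = np.inf
        converged = False
        for _ in range(self.max_iter):
            X = (model.mean_ + Phi @ b).reshape(-1, 3)
            cur = T.apply(X)
            _, idx = tree.query(cur)
            y_t = tgt[idx]                      # correspondence update
            T = kabsch(X, y_t)                  # rigid update
            y_m = T.inverse().apply(y_t)        # targets in model frame
            r = y_m.reshape(-1) - model.mean_
            # rows of Phi are orthonormal columns of components_, so the
            # ridge normal matrix is diagonal
            p = Phi.T @ r
            b = p / (1.0 + n * w / lam[:k])
            X = (model.mean_ + Phi @ b).reshape(-1, 3)
            msd = float(np.mean(np.sum((T.apply(X) - y_t) ** 2, axis=1)))
            F = _surrogate(msd, b, lam, w)
            history.append(F)
            if prev - F < self.tol:
                converged = True
                break
            prev = F
        return self._finish(T, b, tgt, "full", history, converged)


class LandmarkFitter(_BaseFitter):
    """Fit a shape model to three named sparse anatomical landmarks.

    Correspondence is known (landmark name -> model vertex index), so the
    fit alternates a rigid Procrustes solve on the landmark triple with a
    penalized least-squares solve for the mode weights restricted to the
    landmark rows of the mode matrix.  Returns the full reconstructed
    surface.

    Parameters
    ----------
    model : fitted model whose ``landmark_indices_`` (or the ``scheme``
        argument of :meth:`fit`) binds landmark names to vertex indices.
    k : number of modes (default 3, the identifiable maximum for three
        landmarks).
    """

    def __init__(self, model: PointDistributionModel, k: int | None = 3,
                 penalty_weight: float = DEFAULT_PENALTY_WEIGHT,
                 max_iter: int = 200, tol: float = 0.0):
        super().__init__(model, k=k, penalty_weight=penalty_weight,
                         max_iter=max_iter, tol=tol)

    def fit(self, landmarks, y=None, scheme: dict[str, int] | None = None):
        """``landmarks``: a :class:`LandmarkFile` or name -> xyz mapping."""
        model = self.model
        k = self._resolve_k()
        scheme = scheme or model.landmark_indices_
        if not scheme:
            raise LandmarkSchemaError(
                "no landmark scheme: the model has no landmark_indices_ and "
                "none was supplied"
            )
        names = list(scheme)
        if isinstance(landmarks, LandmarkFile):
            if landmarks.segment == "talus":
                raise UnsupportedSegmentError(
                    "the talus is excluded from sparse reconstruction"
                )
            y_t = landmarks.coordinates(names)
        else:
            missing = [nm for nm in names if nm not in landmarks]
            if missing:
                raise LandmarkSchemaError(f"landmark(s) {missing} missing")
            y_t = np.vstack([np.asarray(landmarks[nm], float) for nm in names])
        rows_pts = np.array([scheme[nm] for nm in names], dtype=np.int64)
        if rows_pts.min() < 0 or rows_pts.max() >= model.n_points_:
            raise LandmarkSchemaError("landmark vertex index out of range")
        self._landmark_rows = rows_pts
        rows_coords = (3 * rows_pts[:, None] + np.arange(3)).reshape(-1)

        mean_L = model.mean_.reshape(-1, 3)[rows_pts]
        Phi_L = model.components_[:k].T[rows_coords]  # (3*nL, k)
        lam = model.eigenvalues_
        nL = len(rows_pts)
        w = self.penalty_weight

        b = np.zeros(k)
        T = kabsch(mean_L, y_t)
        history: list[float] = []
        prev = np.inf
        converged = False
        for _ in range(self.max_iter):
            X_L = mean_L + (Phi_L @ b).reshape(-1, 3)
            T = kabsch(X_L, y_t)
            y_m = T.inverse().apply(y_t)
            r = (y_m - mean_L).reshape(-1)
            b = _solve_weights(Phi_L, r, lam, w, nL)
            X_L = mean_L + (Phi_L @ b).reshape(-1, 3)
            msd = float(np.mean(np.sum((T.apply(X_L) - y_t) ** 2, axis=1)))
            F = _surrogate(msd, b, lam, w)
            history.append(F)
            if prev - F < self.tol:
                converged = True
                break
            prev = F
        return self._finish(T, b, y_t, "sparse", history, converged)


def fit_full(model: PointDistributionModel, target,
             k: int | None = None,
             penalty_weight: float = DEFAULT_PENALTY_WEIGHT,
             **kwargs) -> FitResult:
    """Fit the model to a full surface; returns a :class:`FitResult`."""
    return SurfaceFitter(model, k=k, penalty_weight=penalty_weight,
                         **kwargs).fit(target).result_


def fit_sparse(model: PointDistributionModel, landmarks,
               scheme: dict[str, int] | None = None, k: int = 3,
               penalty_weight: float = DEFAULT_PENALTY_WEIGHT,
               **kwargs) -> FitResult:
    """Fit the model to three sparse landmarks; returns a
    :class:`FitResult` with the full reconstructed surface."""
    return LandmarkFitter(model, k=k, penalty_weight=penalty_weight,
                          **kwargs).fit(landmarks, scheme=scheme).result_
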