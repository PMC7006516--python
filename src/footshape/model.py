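"""PCA point-distribution models (statistical shape models).

A shape model is the arithmetic mean of M corresponded shapes (stacked as
3N-vectors) plus an orthonormal basis of principal components with sample
eigenvalues (1/(M-1) normalization).  Shapes are synthesized as

    x(b) = mean + sum_i b_i * mode_i,

and the plausibility of a deformation b is measured by the Mahalanobis
distance sqrt(sum_i b_i^2 / lambda_i) relative to the training variance.

Implemented as a scikit-learn style transformer: ``fit`` on an (M, 3N)
matrix or a :class:`~footshape.registration.CorrespondedSet`; ``transform``
projects shapes to mode weights; ``inverse_transform`` synthesizes shapes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .geometry import GeometryError, PointCloud
from .registration import CorrespondedSet

__all__ = [
    "PointDistributionModel",
    "build_ssm",
    "select_num_components",
]


def select_num_components(ratios, threshold: float = 0.80) -> int:
    """Smallest k whose cumulative explained-variance ratio reaches the
    threshold (default 80%)."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ratios = np.asarray(ratios, float)
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    if k > len(ratios):
        raise ValueError(
            f"cumulative ratio {cum[-1]:.4f} never reaches threshold {threshold}"
        )
    return k


def _as_matrix(X) -> tuple[np.ndarray, "CorrespondedSet | None"]:
    if isinstance(X, CorrespondedSet):
        return X.shapes.reshape(X.n_shapes, -1), X
    arr = np.asarray(X, float)
    if arr.ndim == 3 and arr.shape[2] == 3:
        arr = arr.reshape(arr.shape[0], -1)
    if arr.ndim != 2 or arr.shape[1] % 3:
        raise GeometryError(
            f"expected (M, 3N) or (M, N, 3) training data, got {arr.shape}"
        )
    return arr, None


class PointDistributionModel(TransformerMixin, BaseEstimator):
    """Statistical shape model over corresponded point clouds.

    Parameters
    ----------
    n_components : number of modes to keep; ``None`` keeps the full rank
        min(M - 1, 3N).
    segment : segment label stored with the model.

    Attributes
    ----------
    mean_ : (3N,) mean shape vector (mm), template ordering.
    components_ : (K, 3N) orthonormal principal components (rows).
    eigenvalues_ : (K,) non-increasing sample variances (mm^2).
    explained_variance_ratio_ : eigenvalues / total variance.
    n_training_ : number of training shapes M.
    n_points_ : N.
    landmark_indices_ : optional landmark-name -> vertex-index map.
    faces_ : optional template faces for surfacing synthesized shapes.
    """

    def __init__(self, n_components: int | None = None, segment: str | None = None):
        self.n_components = n_components
        self.segment = segment

    # -- construction ------------------------------------------------------

    def fit(self, X, y=None, landmark_indices: dict[str, int] | None = None):
        mat, corr = _as_matrix(X)
        M = mat.shape[0]
        if M < 3:
            raise GeometryError(f"need at least 3 corresponded shapes, got {M}")
        max_rank = min(M - 1, mat.shape[1])
        k = max_rank if self.n_components is None else int(self.n_components)
        if k > max_rank:
            raise GeometryError(f"n_components={k} exceeds rank {max_rank}")
        # sklearn's full-SVD PCA: 1/(M-1) eigenvalues and the deterministic
        # svd_flip sign convention (largest-|coefficient| positive)
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(mat)
        # total variance over all directions, so ratios are comparable
        # whatever k is kept
        total = np.var(mat, axis=0, ddof=1).sum()
        self.mean_ = pca.mean_
        self.components_ = pca.components_
        self.eigenvalues_ = pca.explained_variance_
        self._total_variance = float(total)
        self.explained_variance_ratio_ = (
            self.eigenvalues_ / total if total > 0 else np.zeros(k)
        )
        self.n_training_ = M
        self.n_points_ = mat.shape[1] // 3
        self.segment_ = self.segment or (corr.template.label if corr else None)
        self.landmark_indices_ = dict(landmark_indices) if landmark_indices else None
        self.faces_ = corr.faces if corr is not None else None
        return self

    @classmethod
    def _from_arrays(cls, mean, components, eigenvalues, n_training,
                     segment=None, landmark_indices=None, faces=None,
                     total_variance=None):
        m = cls(segment=segment)
        m.mean_ = np.asarray(mean, float)
        m.components_ = np.asarray(components, float)
        m.eigenvalues_ = np.asarray(eigenvalues, float)
        m._total_variance = float(m.eigenvalues_.sum()) \
            if total_variance is None else float(total_variance)
        m.explained_variance_ratio_ = (
            m.eigenvalues_ / m._total_variance if m._total_variance > 0
            else np.zeros(len(m.eigenvalues_))
        )
        m.n_training_ = int(n_training)
        m.n_points_ = m.mean_.size // 3
        m.segment_ = segment
        m.landmark_indices_ = landmark_indices
        m.faces_ = faces
        return m

    def _check_fitted(self):
        if not hasattr(self, "mean_"):
            raise RuntimeError("model is not fitted")

    # -- queries -----------------------------------------------------------

    @property
    def n_modes(self) -> int:
        self._check_fitted()
        return self.components_.shape[0]

    def explained_variance(self) -> np.ndarray:
        """Per-mode explained-variance ratios (non-increasing)."""
        self._check_fitted()
        return self.explained_variance_ratio_

    def select_num_components(self, threshold: float = 0.80) -> int:
        """Smallest number of modes reaching the variance threshold."""
        return select_num_components(self.explained_variance_ratio_, threshold)

    def transform(self, X) -> np.ndarray:
        """Project shapes onto the modes: b = components (x - mean)."""
        self._check_fitted()
        mat, _ = _as_matrix(np.atleast_2d(np.asarray(X, float))
                            if not isinstance(X, CorrespondedSet) else X)
        return (mat - self.mean_) @ self.components_.T

    def inverse_transform(self, b) -> np.ndarray:
        """Synthesize (stacked) shape vectors from mode weights."""
        self._check_fitted()
        b = np.atleast_2d(np.asarray(b, float))
        if b.shape[1] > self.n_modes:
            raise GeometryError(f"{b.shape[1]} weights but model has {self.n_modes} modes")
        return self.mean_ + b @ self.components_[: b.shape[1]]

    def generate_shape(self, b=None) -> PointCloud:
        """Synthesize a shape as an (N, 3) point cloud; b=None gives the
        mean shape."""
        self._check_fitted()
        if b is None:
            b = np.zeros(0)
        vec = self.inverse_transform(np.asarray(b, float).reshape(1, -1))[0] \
            if np.asarray(b).size else self.mean_
        return PointCloud(vec.reshape(-1, 3), label=self.segment_, side="right")

    def mahalanobis(self, b) -> float:
        """Shape-prior Mahalanobis distance sqrt(sum b_i^2 / lambda_i)."""
        self._check_fitted()
        b = np.asarray(b, float).reshape(-1)
        lam = self.eigenvalues_[: len(b)]
        if np.any(lam <= 0):
            raise GeometryError(
                "zero eigenvalue among used modes; truncate n_components to "
                "the non-degenerate modes"
            )
        return float(np.sqrt(np.sum(b**2 / lam)))


def build_ssm(corr: CorrespondedSet, n_components: int | None = None,
              landmark_indices: dict[str, int] | None = None) -> PointDistributionModel:
    """Build a point-distribution model from a corresponded set."""
    return PointDistributionModel(n_components=n_components).fit(
        corr, landmark_indices=landmark_indices
    )
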