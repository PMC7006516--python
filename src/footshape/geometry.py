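"""Geometry primitives for bone-surface shape modelling.

Point clouds and triangle meshes in millimetres, rigid homogeneous
transforms, left/right mirroring, anatomical coordinate frames, solid
voxelization and nearest-neighbour queries.  Everything downstream
(registration, PCA shape models, validation metrics) is built on these
carriers.

Conventions
-----------
* All coordinates are millimetres.
* Point ordering is significant once correspondence has been established:
  index ``i`` refers to the same anatomical location on every corresponded
  cloud.
* Rigid transforms are pure rotations + translations (det(R) = +1);
  mirroring is an explicit, separate operation and is never encoded in a
  :class:`RigidTransform`.
* For a right-side segment the anatomical frame is x anterior, y proximal,
  z lateral (right-handed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "TriangleMesh",
    "RigidTransform",
    "AnatomicalFrame",
    "VoxelGrid",
    "GeometryError",
    "TransformError",
    "DegenerateFrameError",
    "WatertightnessError",
    "apply_transform",
    "mirror",
    "anatomical_frame_from_landmarks",
    "frame_to_transform",
    "voxelize",
    "occupancy_on_grid",
    "nearest_neighbour_distances",
]

SEGMENTS = ("first_metatarsal", "midfoot", "calcaneus", "talus", "synthetic")

_ORTHO_TOL = 1e-9


class GeometryError(ValueError):
    """Invalid geometric input (empty, non-finite, malformed)."""


class TransformError(GeometryError):
    """Matrix is not a valid rigid (rotation + translation) transform."""


class DegenerateFrameError(GeometryError):
    """Landmarks are collinear; no anatomical frame can be built."""


class WatertightnessError(GeometryError):
    """Mesh is not closed; volumetric operations refuse it."""

    def __init__(self, open_edge_count: int):
        self.open_edge_count = open_edge_count
        super().__init__(
            f"mesh is not watertight: {open_edge_count} open (boundary) edges; "
            "volumetric operations require a closed surface"
        )


@dataclass(frozen=True)
class PointCloud:
    """Ordered 3D point set in millimetres.

    Parameters
    ----------
    points : (N, 3) float array, N >= 4, finite.
    label : segment identifier; one of :data:`SEGMENTS` or ``None``.
    side : ``"left"``, ``"right"`` or ``"none"``.
    """

    points: np.ndarray
    label: str | None = None
    side: str = "none"

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise GeometryError(f"points must be (N, 3), got {pts.shape}")
        if pts.shape[0] < 4:
            raise GeometryError(f"need at least 4 points, got {pts.shape[0]}")
        if not np.isfinite(pts).all():
            raise GeometryError("points contain non-finite coordinates")
        if self.side not in ("left", "right", "none"):
            raise GeometryError(f"side must be left/right/none, got {self.side!r}")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    def with_points(self, points: np.ndarray) -> "PointCloud":
        return replace(self, points=points)


@dataclass(frozen=True)
class TriangleMesh:
    """Triangle surface mesh: vertices as a :class:`PointCloud` plus faces.

    Faces are vertex-index triples.  Meshes used for volumetric metrics
    must be watertight and positively oriented (signed volume > 0).
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str | None = None
    side: str = "none"

    def __post_init__(self):
        verts = np.asarray(self.vertices, dtype=float)
        faces = np.asarray(self.faces, dtype=np.int64)
        if verts.ndim != 2 or verts.shape[1] != 3:
            raise GeometryError(f"vertices must be (N, 3), got {verts.shape}")
        if not np.isfinite(verts).all():
            raise GeometryError("vertices contain non-finite coordinates")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise GeometryError(f"faces must be (F, 3), got {faces.shape}")
        if faces.size and (faces.min() < 0 or faces.max() >= len(verts)):
            raise GeometryError("face index out of range")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "faces", faces)

    def as_cloud(self) -> PointCloud:
        return PointCloud(self.vertices, label=self.label, side=self.side)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def is_watertight(self) -> bool:
        return self.to_trimesh().is_watertight

    @property
    def open_edge_count(self) -> int:
        tm = self.to_trimesh()
        edges = tm.edges_sorted
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int((counts != 2).sum())

    @property
    def volume(self) -> float:
        """Signed volume via the divergence theorem (mm^3)."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0)

    def oriented(self) -> "TriangleMesh":
        """Return the mesh with faces flipped if signed volume is negative."""
        if self.volume < 0:
            return replace(self, faces=self.faces[:, ::-1])
        return self

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        return replace(self, vertices=vertices)


@dataclass(frozen=True)
class RigidTransform:
    """4x4 homogeneous rigid transform: rotation block R, translation t.

    R must be orthonormal with det(R) = +1 (within 1e-9).  Reflections are
    rejected; mirroring is handled by :func:`mirror`, never here.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise TransformError(f"matrix must be 4x4, got {m.shape}")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=_ORTHO_TOL):
            raise TransformError("bottom row must be (0, 0, 0, 1)")
        R = m[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise TransformError("rotation block is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=_ORTHO_TOL):
            raise TransformError(
                "rotation block has det != +1 (reflections are not rigid "
                "transforms here; use mirror())"
            )
        object.__setattr__(self, "matrix", m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = np.asarray(t, dtype=float).reshape(3)
        return cls(m)

    def inverse(self) -> "RigidTransform":
        R, t = self.rotation, self.translation
        return RigidTransform.from_rotation_translation(R.T, -R.T @ t)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (apply ``other`` first)."""
        return RigidTransform(self.matrix @ other.matrix)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation


@dataclass(frozen=True)
class AnatomicalFrame:
    """Body-fixed coordinate system: origin + three orthonormal axes.

    Axes are rows of ``axes``; right-handed (x cross y = z).  For a
    right-side foot segment: x anterior, y proximal, z lateral.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        ax = np.asarray(self.axes, dtype=float)
        if ax.shape != (3, 3):
            raise GeometryError(f"axes must be 3x3, got {ax.shape}")
        if not np.allclose(ax @ ax.T, np.eye(3), atol=_ORTHO_TOL):
            raise DegenerateFrameError("axes are not orthonormal")
        if not np.allclose(np.cross(ax[0], ax[1]), ax[2], atol=_ORTHO_TOL):
            raise DegenerateFrameError("axes are not right-handed")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axes", ax)


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned occupancy grid: origin (mm), isotropic voxel size (mm),
    boolean occupancy array.  Voxel (i, j, k) has its centre at
    ``origin + (i + 0.5, j + 0.5, k + 0.5) * voxel_size``."""

    origin: np.ndarray
    voxel_size: float
    occupancy: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise GeometryError("voxel_size must be > 0")
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.ndim != 3:
            raise GeometryError("occupancy must be a 3D boolean array")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        object.__setattr__(self, "occupancy", occ)

    @property
    def occupied_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume(self) -> float:
        """Occupied volume estimate in mm^3."""
        return self.occupied_count * self.voxel_size**3


# ---------------------------------------------------------------------------
# operations


def apply_transform(cloud: PointCloud, transform: RigidTransform) -> PointCloud:
    """Map every point p -> R p + t; ordering, label and side preserved."""
    return cloud.with_points(transform.apply(cloud.points))


_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}
_SIDE_FLIP = {"left": "right", "right": "left", "none": "none"}


def mirror(obj: PointCloud | TriangleMesh, axis: str = "z"):
    """Reflect about the plane normal to ``axis`` (coordinate negated).

    The side flag flips left<->right.  For meshes, face winding is reversed
    so the signed volume stays positive.  Mirroring twice is the identity.
    """
    try:
        k = _AXIS_INDEX[axis]
    except KeyError:
        raise GeometryError(f"axis must be one of x/y/z, got {axis!r}") from None
    if isinstance(obj, TriangleMesh):
        verts = obj.vertices.copy()
        verts[:, k] = -verts[:, k]
        return replace(obj, vertices=verts, faces=obj.faces[:, ::-1],
                       side=_SIDE_FLIP[obj.side])
    pts = obj.points.copy()
    pts[:, k] = -pts[:, k]
    return replace(obj, points=pts, side=_SIDE_FLIP[obj.side])


def anatomical_frame_from_landmarks(p_origin, p_axis1, p_plane) -> AnatomicalFrame:
    """Build a right-handed frame from three non-collinear landmarks.

    First axis along ``p_axis1 - p_origin``; third axis along the normal of
    the plane spanned by the three points; second axis completes the triad
    (Gram-Schmidt).
    """
    p0 = np.asarray(p_origin, dtype=float).reshape(3)
    p1 = np.asarray(p_axis1, dtype=float).reshape(3)
    p2 = np.asarray(p_plane, dtype=float).reshape(3)
    e1 = p1 - p0
    n1 = np.linalg.norm(e1)
    normal = np.cross(e1, p2 - p0)
    n3 = np.linalg.norm(normal)
    # collinearity threshold relative to the landmark scale
    scale = max(n1, np.linalg.norm(p2 - p0), 1.0)
    if n1 < 1e-12 or n3 < 1e-12 * scale**2:
        raise DegenerateFrameError("landmarks are collinear or coincident")
    x = e1 / n1
    z = normal / n3
    y = np.cross(z, x)
    return AnatomicalFrame(origin=p0, axes=np.vstack([x, y, z]))


def frame_to_transform(frame: AnatomicalFrame) -> RigidTransform:
    """Transform mapping world coordinates into the frame.

    The frame origin maps to (0, 0, 0) and the frame axes to the standard
    basis: ``p -> A (p - origin)`` with A the (row-stacked) axes matrix.
    """
    return RigidTransform.from_rotation_translation(
        frame.axes, -frame.axes @ frame.origin
    )


def _rasterize_inside(mesh: TriangleMesh, centres_xy, z_edges, grid_shape):
    """Z-ray parity rasterizer.

    For each (x, y) column of voxel centres, intersect the vertical ray with
    every triangle and mark centres between odd/even crossing pairs as
    inside.  A half-open fill rule on the projected triangles (strict on two
    edges, inclusive on the others, via a top-left style tie-break) counts
    every crossing exactly once for a watertight mesh.
    """
    nx, ny, nz = grid_shape
    xs, ys = centres_xy
    occ = np.zeros((nx, ny, nz), dtype=bool)
    v = mesh.vertices
    tris = v[mesh.faces]  # (F, 3, 3)

    # crossing z-values per column, accumulated per triangle
    crossings = [[] for _ in range(nx * ny)]
    for tri in tris:
        (x0, y0, z0), (x1, y1, z1), (x2, y2, z2) = tri
        # signed area of projection on xy; skip vertical triangles
        area = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if area == 0.0:
            continue
        if area < 0:  # normalize to CCW in projection
            (x1, y1, z1), (x2, y2, z2) = (x2, y2, z2), (x1, y1, z1)
            area = -area
        lo_x, hi_x = min(x0, x1, x2), max(x0, x1, x2)
        lo_y, hi_y = min(y0, y1, y2), max(y0, y1, y2)
        i0 = np.searchsorted(xs, lo_x, side="left")
        i1 = np.searchsorted(xs, hi_x, side="right")
        j0 = np.searchsorted(ys, lo_y, side="left")
        j1 = np.searchsorted(ys, hi_y, side="right")
        if i0 >= i1 or j0 >= j1:
            continue
        gx = xs[i0:i1][:, None]
        gy = ys[j0:j1][None, :]
        # edge functions (positive inside for CCW)
        e0 = (x1 - x0) * (gy - y0) - (y1 - y0) * (gx - x0)
        e1_ = (x2 - x1) * (gy - y1) - (y2 - y1) * (gx - x1)
        e2 = (x0 - x2) * (gy - y2) - (y0 - y2) * (gx - x2)

        def top_left(ax, ay, bx, by):
            dy = by - ay
            dx = bx - ax
            return dy < 0 or (dy == 0 and dx > 0)

        inc0 = e0 >= 0 if top_left(x0, y0, x1, y1) else e0 > 0
        inc1 = e1_ >= 0 if top_left(x1, y1, x2, y2) else e1_ > 0
        inc2 = e2 >= 0 if top_left(x2, y2, x0, y0) else e2 > 0
        inside = inc0 & inc1 & inc2
        if not inside.any():
            continue
        # barycentric z interpolation
        w0 = e1_ / area
        w1 = e2 / area
        w2 = e0 / area
        zc = w0 * z0 + w1 * z1 + w2 * z2
        ii, jj = np.nonzero(inside)
        for a, b in zip(ii, jj):
            crossings[(i0 + a) * ny + (j0 + b)].append(zc[a, b])

    zc_centres = z_edges  # voxel-centre z coordinates
    for idx, cs in enumerate(crossings):
        if not cs:
            continue
        cs = sorted(cs)
        if len(cs) % 2:
            # ray grazed an edge despite the fill rule; drop the closest pair
            continue
        i, j = divmod(idx, ny)
        col = np.zeros(nz, dtype=bool)
        for lo, hi in zip(cs[::2], cs[1::2]):
            col |= (zc_centres > lo) & (zc_centres < hi)
        occ[i, j] = col
    return occ


def occupancy_on_grid(mesh: TriangleMesh, origin: np.ndarray,
                      shape: tuple[int, int, int], voxel_size: float) -> VoxelGrid:
    """Voxelize a watertight mesh onto a caller-specified grid (used to put
    two meshes on one shared grid for volumetric overlap)."""
    if voxel_size <= 0:
        raise GeometryError("voxel_size must be > 0")
    if not mesh.is_watertight:
        raise WatertightnessError(mesh.open_edge_count)
    origin = np.asarray(origin, float).reshape(3)
    nx, ny, nz = shape
    xs = origin[0] + (np.arange(nx) + 0.5) * voxel_size
    ys = origin[1] + (np.arange(ny) + 0.5) * voxel_size
    zs = origin[2] + (np.arange(nz) + 0.5) * voxel_size
    occ = _rasterize_inside(mesh, (xs, ys), zs, (nx, ny, nz))
    return VoxelGrid(origin=origin, voxel_size=voxel_size, occupancy=occ)


def voxelize(mesh: TriangleMesh, voxel_size: float = 0.59) -> VoxelGrid:
    """Voxelize a watertight mesh: occupancy true exactly for voxel centres
    strictly inside the closed surface (half-open grid convention).

    The default voxel size of 0.59 mm matches typical high-resolution MRI
    pixel spacing for the foot.  Grid bounds cover the mesh bounding box
    padded by at least one voxel.
    """
    if voxel_size <= 0:
        raise GeometryError("voxel_size must be > 0")
    if not mesh.is_watertight:
        raise WatertightnessError(mesh.open_edge_count)
    lo = mesh.vertices.min(axis=0) - voxel_size
    hi = mesh.vertices.max(axis=0) + voxel_size
    n = np.ceil((hi - lo) / voxel_size).astype(int)
    origin = lo
    xs = origin[0] + (np.arange(n[0]) + 0.5) * voxel_size
    ys = origin[1] + (np.arange(n[1]) + 0.5) * voxel_size
    zs = origin[2] + (np.arange(n[2]) + 0.5) * voxel_size
    occ = _rasterize_inside(mesh, (xs, ys), zs, tuple(n))
    return VoxelGrid(origin=origin, voxel_size=voxel_size, occupancy=occ)


def nearest_neighbour_distances(source: PointCloud | np.ndarray,
                                target: PointCloud | np.ndarray) -> np.ndarray:
    """Euclidean distance from each source point to its nearest target point.

    Uses a k-d tree; agrees with exhaustive search exactly.
    """
    src = source.points if isinstance(source, PointCloud) else np.asarray(source, float)
    tgt = target.points if isinstance(target, PointCloud) else np.asarray(target, float)
    if src.size == 0 or tgt.size == 0:
        raise GeometryError("nearest-neighbour query on empty cloud")
    d, _ = cKDTree(tgt).query(src)
    return d
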