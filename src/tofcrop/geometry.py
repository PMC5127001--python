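"""Sensor frustum geometry, rigid transforms and robust plane fitting.

The depth camera modelled here is a pinhole time-of-flight sensor: a
rectangular pixel grid of ``n_cols x n_rows`` rays spanning a full
horizontal angle ``h_fov`` and vertical angle ``v_fov``.  Its viewing
volume is a truncated pyramid (frustum): four angular side planes plus a
near and a far cap.  Range limits are expressed as *sensor-frame depth*
(the z coordinate in the sensor frame, i.e. the value a depth image
stores per pixel), not Euclidean ray length — a flat target filling the
field of view at depth ``d`` therefore returns every pixel as long as
``min_range <= d <= max_range``, even though corner rays are up to
``d / cos(theta_corner)`` long.

Conventions used throughout the package:

* world frame is Z-up, metres everywhere;
* the sensor frame is x-right (columns, spanning ``h_fov``), y-down the
  row axis (spanning ``v_fov``), z along the boresight;
* a nadir pose maps the boresight to world -Z, so elevations of
  measured points are plain world z values.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "FrustumSpec",
    "SensorPose",
    "PointCloud",
    "RigidTransform",
    "PlaneModel",
    "theoretical_spacing",
    "frustum_contains",
    "clip_to_top_fov",
    "fit_plane_ransac",
    "frustum_face_distances",
    "frustum_boundary_mesh",
]


# ---------------------------------------------------------------------------
# Domain types


class DomainError(ValueError):
    """Raised when an argument violates a geometric precondition."""


@dataclass(frozen=True)
class FrustumSpec:
    """Field-of-view geometry of a depth sensor.

    Defaults describe the Kinect for Xbox One time-of-flight camera:
    70 x 60 degree field of view, 512 x 424 pixels, usable depth range
    0.5-4.5 m.
    """

    h_fov: float = 70.0
    v_fov: float = 60.0
    n_cols: int = 512
    n_rows: int = 424
    min_range: float = 0.5
    max_range: float = 4.5

    def __post_init__(self) -> None:
        if not (0.0 < self.h_fov < 180.0 and 0.0 < self.v_fov < 180.0):
            raise DomainError("field-of-view angles must lie in (0, 180) degrees")
        if self.n_cols < 1 or self.n_rows < 1:
            raise DomainError("pixel counts must be >= 1")
        if not (0.0 < self.min_range < self.max_range):
            raise DomainError("require 0 < min_range < max_range")

    @property
    def n_pixels(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def tan_h(self) -> float:
        """Tangent of the horizontal half angle."""
        return math.tan(math.radians(self.h_fov) / 2.0)

    @property
    def tan_v(self) -> float:
        """Tangent of the vertical half angle."""
        return math.tan(math.radians(self.v_fov) / 2.0)


@dataclass(frozen=True)
class SensorPose:
    """Rigid placement of a sensor in the world frame.

    ``rotation`` columns are the sensor axes expressed in world
    coordinates; it must be a proper rotation (orthonormal, det +1).
    """

    origin: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-8):
            raise DomainError("rotation must be orthonormal")
        if np.linalg.det(rotation) < 0.0:
            raise DomainError("rotation must be proper (det +1)")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "rotation", rotation)

    @classmethod
    def nadir(cls, origin, boresight_x_world=(0.0, 1.0, 0.0)) -> "SensorPose":
        """Pose looking straight down (boresight = world -Z).

        ``boresight_x_world`` is the world direction of the sensor's
        column axis (the wide ``h_fov`` direction); default along +Y,
        matching a sensor mounted parallel to a plot's long edge.
        """
        x_s = np.asarray(boresight_x_world, dtype=float)
        x_s = x_s / np.linalg.norm(x_s)
        z_s = np.array([0.0, 0.0, -1.0])
        y_s = np.cross(z_s, x_s)
        rotation = np.column_stack([x_s, y_s, z_s])
        return cls(origin=np.asarray(origin, dtype=float), rotation=rotation)

    def to_sensor(self, points: np.ndarray) -> np.ndarray:
        """World -> sensor frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.origin) @ self.rotation

    def to_world(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.origin


class PointCloud:
    """A set of XYZ coordinates (metres) with optional per-point attributes.

    ``xyz`` is an (n, 3) float64 array; ``attributes`` maps names to
    length-n arrays (e.g. a source pose id).  The class is deliberately
    minimal — numpy arrays are the working currency of the pipeline.
    """

    def __init__(self, xyz, attributes: dict | None = None):
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        if xyz.size and not np.all(np.isfinite(xyz)):
            raise DomainError("point coordinates must be finite")
        self.xyz = xyz
        self.attributes: dict[str, np.ndarray] = {}
        for name, values in (attributes or {}).items():
            values = np.asarray(values)
            if values.shape[0] != len(xyz):
                raise DomainError(
                    f"attribute {name!r} has {values.shape[0]} values "
                    f"for {len(xyz)} points"
                )
            self.attributes[name] = values

    def __len__(self) -> int:
        return self.xyz.shape[0]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        names = ", ".join(self.attributes) or "none"
        return f"PointCloud({len(self)} points, attributes: {names})"

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def select(self, index) -> "PointCloud":
        """Subset by boolean mask or integer index array."""
        return PointCloud(
            self.xyz[index],
            {name: values[index] for name, values in self.attributes.items()},
        )

    def transformed(self, transform: "RigidTransform") -> "PointCloud":
        return PointCloud(transform.apply(self.xyz), dict(self.attributes))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: ``p -> rotation @ p + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-8):
            raise DomainError("rotation must be orthonormal")
        if np.linalg.det(rotation) < 0.0:
            raise DomainError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", rotation)
        object.__setattr__(self, "translation", translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class PlaneModel:
    """Plane ``normal . p = offset`` with the RANSAC inlier mask.

    ``offset`` is the signed distance of the plane from the origin along
    the (unit) normal; residual of a point p is ``normal . p - offset``.
    """

    normal: np.ndarray
    offset: float
    inlier_mask: np.ndarray

    def residuals(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.normal - self.offset


# ---------------------------------------------------------------------------
# Operations


def theoretical_spacing(range_m: float, full_angle_deg: float, n_pixels: int) -> float:
    """Theoretical spacing of range measurements at a given range.

    The image plane at range r spans ``2 r tan(full_angle / 2)`` across
    ``n_pixels`` pixels, so neighbouring measurements are separated by
    ``2 r tan(full_angle / 2) / n_pixels`` metres.
    """
    if range_m <= 0:
        raise DomainError("range must be positive")
    if not (0.0 < full_angle_deg < 180.0):
        raise DomainError("full angle must lie in (0, 180) degrees")
    if n_pixels < 1:
        raise DomainError("pixel count must be >= 1")
    return 2.0 * range_m * math.tan(math.radians(full_angle_deg) / 2.0) / n_pixels


def frustum_contains(points, pose: SensorPose, spec: FrustumSpec) -> np.ndarray:
    """True for points inside the sensor's viewing frustum (closed).

    A point is contained when its sensor-frame depth z lies in
    ``[min_range, max_range]`` and its angular offsets are within half
    the field of view, i.e. ``|x| <= z tan(h_fov/2)`` and
    ``|y| <= z tan(v_fov/2)``.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    s = pose.to_sensor(pts)
    z = s[:, 2]
    inside = (
        (z >= spec.min_range)
        & (z <= spec.max_range)
        & (np.abs(s[:, 0]) <= z * spec.tan_h)
        & (np.abs(s[:, 1]) <= z * spec.tan_v)
    )
    return bool(inside[0]) if single else inside


def clip_to_top_fov(
    cloud: PointCloud, pose: SensorPose, spec: FrustumSpec, top_range: float
) -> PointCloud:
    """Clip a cloud to the FOV cross-section at the canopy-top range.

    ``top_range`` is the sensor-to-highest-plant distance; the retained
    points are those whose sensor-frame lateral coordinates fall inside
    the (closed) FOV rectangle evaluated at that depth.  This removes
    the splayed lower margin of the frustum together with the edge
    artefacts that concentrate on the FOV faces.
    """
    if not (spec.min_range <= top_range <= spec.max_range):
        raise DomainError(
            f"top_range {top_range} outside [{spec.min_range}, {spec.max_range}]"
        )
    s = pose.to_sensor(cloud.xyz)
    keep = (np.abs(s[:, 0]) <= top_range * spec.tan_h) & (
        np.abs(s[:, 1]) <= top_range * spec.tan_v
    )
    return cloud.select(keep)


def fit_plane_ransac(
    cloud: PointCloud | np.ndarray,
    dist_threshold: float = 0.01,
    iterations: int = 500,
    seed: int = 0,
) -> PlaneModel:
    """Robust plane fit by random sample consensus.

    Repeatedly draws 3-point samples, keeps the candidate plane with the
    most points within ``dist_threshold``, then refines it by a total
    least-squares fit (SVD) on the inliers and recomputes the mask.
    Deterministic for a given ``seed``.
    """
    pts = cloud.xyz if isinstance(cloud, PointCloud) else np.asarray(cloud, float)
    n = len(pts)
    if n < 3:
        raise DomainError("plane fit needs at least 3 points")
    rng = np.random.default_rng(seed)

    best_count = -1
    best_normal = None
    best_offset = 0.0
    for _ in range(iterations):
        idx = rng.choice(n, size=3, replace=False)
        a, b, c = pts[idx]
        normal = np.cross(b - a, c - a)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:  # collinear sample
            continue
        normal = normal / norm
        offset = normal @ a
        count = int(np.sum(np.abs(pts @ normal - offset) <= dist_threshold))
        if count > best_count:
            best_count, best_normal, best_offset = count, normal, offset
    if best_normal is None:
        raise DomainError("degenerate input: no non-collinear 3-point sample found")

    inliers = np.abs(pts @ best_normal - best_offset) <= dist_threshold
    if inliers.sum() >= 3:
        centred = pts[inliers] - pts[inliers].mean(axis=0)
        # total least squares: normal = singular vector of smallest s.v.
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        normal = vt[-1]
        offset = float(normal @ pts[inliers].mean(axis=0))
        inliers = np.abs(pts @ normal - offset) <= dist_threshold
    else:
        normal, offset = best_normal, best_offset

    # canonical orientation: normal points towards +z (ties: +y, then +x)
    for axis in (2, 1, 0):
        if abs(normal[axis]) > 1e-12:
            if normal[axis] < 0:
                normal, offset = -normal, -offset
            break
    return PlaneModel(normal=normal, offset=float(offset), inlier_mask=inliers)


def frustum_boundary_mesh(pose: SensorPose, spec: FrustumSpec) -> np.ndarray:
    """Triangulated frustum boundary in world coordinates.

    The truncated pyramid has 8 corners (FOV rectangle at ``min_range``
    and at ``max_range``); its 6 quadrilateral faces are split into 12
    triangles, returned as an array of shape (12, 3, 3).
    """
    corners = []
    for z in (spec.min_range, spec.max_range):
        hx, hy = z * spec.tan_h, z * spec.tan_v
        for sy in (-1.0, 1.0):
            for sx in (-1.0, 1.0):
                corners.append([sx * hx, sy * hy, z])
    corners = pose.to_world(np.asarray(corners))
    # corner order per cap: (-x,-y), (+x,-y), (-x,+y), (+x,+y); near 0-3, far 4-7
    quads = [
        (0, 1, 3, 2),  # near cap
        (4, 6, 7, 5),  # far cap
        (0, 2, 6, 4),  # -x side
        (1, 5, 7, 3),  # +x side
        (0, 4, 5, 1),  # -y side
        (2, 3, 7, 6),  # +y side
    ]
    tris = []
    for a, b, c, d in quads:
        tris.append(corners[[a, b, c]])
        tris.append(corners[[a, c, d]])
    return np.asarray(tris)


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distances from each point to one triangle (vectorised over points)."""
    v0, v1, v2 = tri
    e1, e2 = v1 - v0, v2 - v0
    normal = np.cross(e1, e2)
    nn = normal @ normal
    w = points - v0
    # barycentric coordinates of the in-plane projection
    d11, d12, d22 = e1 @ e1, e1 @ e2, e2 @ e2
    w1, w2 = w @ e1, w @ e2
    det = d11 * d22 - d12 * d12
    u = (d22 * w1 - d12 * w2) / det
    v = (d11 * w2 - d12 * w1) / det
    inside = (u >= 0) & (v >= 0) & (u + v <= 1)
    dist = np.full(len(points), np.inf)
    if inside.any():
        dist[inside] = np.abs(w[inside] @ normal) / math.sqrt(nn)
    outside = ~inside
    if outside.any():
        po = points[outside]
        best = np.full(po.shape[0], np.inf)
        for a, b in ((v0, v1), (v1, v2), (v2, v0)):
            ab = b - a
            t = np.clip((po - a) @ ab / (ab @ ab), 0.0, 1.0)
            closest = a + t[:, None] * ab
            best = np.minimum(best, np.linalg.norm(po - closest, axis=1))
        dist[outside] = best
    return dist


def point_mesh_distances(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Shortest Euclidean distance from each point to a triangle soup."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dist = np.full(len(pts), np.inf)
    for tri in triangles:
        dist = np.minimum(dist, _point_triangle_distance(pts, tri))
    return dist


def frustum_face_distances(
    cloud: PointCloud, pose: SensorPose, spec: FrustumSpec
) -> np.ndarray:
    """Per-point shortest distance to the frustum boundary surface.

    Used to characterise measurement artefacts, which concentrate on
    the FOV faces of time-of-flight cameras.
    """
    if len(cloud) == 0:
        return np.empty(0)
    return point_mesh_distances(cloud.xyz, frustum_boundary_mesh(pose, spec))


def rotation_from_vectors(target: np.ndarray, source: np.ndarray) -> np.ndarray:
    """Least-squares rotation mapping source vectors onto target vectors."""
    rot, _ = Rotation.align_vectors(np.atleast_2d(target), np.atleast_2d(source))
    return rot.as_matrix()
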