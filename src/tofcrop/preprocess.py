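"""Point-cloud pre-processing: outlier removal, registration, merging, cropping.

The processing chain applied to every depth-camera frame before height
modelling is fixed: clip to the canopy-top field of view
(:func:`tofcrop.geometry.clip_to_top_fov`), crop to the area of
interest, then statistical outlier removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry import DomainError, PointCloud, RigidTransform

__all__ = [
    "TiePointSet",
    "RegistrationReport",
    "sor_filter",
    "rigid_from_tiepoints",
    "merge_clouds",
    "crop_to_aoi",
    "read_tiepoints_csv",
    "retention_percent",
]


@dataclass(frozen=True)
class TiePointSet:
    """Corresponding point pairs (source, target) for rigid registration."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        source = np.asarray(self.source, dtype=float).reshape(-1, 3)
        target = np.asarray(self.target, dtype=float).reshape(-1, 3)
        if source.shape != target.shape:
            raise DomainError("source and target must pair up one-to-one")
        if len(source) < 3:
            raise DomainError("a unique rigid solution needs >= 3 tie point pairs")
        if len(np.unique(source, axis=0)) != len(source):
            raise DomainError("duplicated source tie points")
        object.__setattr__(self, "source", source)
        object.__setattr__(self, "target", target)

    def __len__(self) -> int:
        return len(self.source)


@dataclass(frozen=True)
class RegistrationReport:
    """Estimated rigid transform plus residual 3D distances per pair."""

    transform: RigidTransform
    residuals: np.ndarray

    @property
    def residual_sd(self) -> float:
        """Standard deviation of the residual 3D distances (metres)."""
        return float(np.std(self.residuals, ddof=1)) if len(self.residuals) > 1 else 0.0


def sor_filter(
    cloud: PointCloud,
    k: int = 5,
    multiplier: float = 1.0,
    literal: bool = False,
) -> tuple[PointCloud, PointCloud]:
    """Statistical outlier removal.

    For each point the mean Euclidean distance ``d_i`` to its ``k``
    nearest neighbours is computed with an exact KD-tree.  A point is
    removed when ``d_i`` strictly exceeds ``mean(d) + multiplier * SD(d)``
    (the classical rule).  With ``literal=True`` the threshold is
    ``multiplier * SD(d)`` alone — that variant removes nearly every
    point on fine, evenly spaced clouds and exists only for comparison.

    Returns ``(kept, removed)``; the two partitions are disjoint and
    their union is the input.
    """
    n = len(cloud)
    if n <= k:
        raise DomainError(f"SOR filter needs more than k={k} points, got {n}")
    tree = cKDTree(cloud.xyz)
    # k+1 because the nearest neighbour of a point is itself
    dists, _ = tree.query(cloud.xyz, k=k + 1)
    mean_dist = dists[:, 1:].mean(axis=1)
    sd = float(np.std(mean_dist))
    threshold = multiplier * sd if literal else float(np.mean(mean_dist)) + multiplier * sd
    outlier = mean_dist > threshold
    return cloud.select(~outlier), cloud.select(outlier)


def rigid_from_tiepoints(ties: TiePointSet) -> RegistrationReport:
    """Least-squares rigid transform (no scale) from tie point pairs.

    Closed-form Kabsch/Horn solution: rotation from the SVD of the
    cross-covariance of the centred pairs, translation from the
    centroids.  Deterministic and exactly invariant to pair order.
    """
    src, tgt = ties.source, ties.target
    src_c, tgt_c = src.mean(axis=0), tgt.mean(axis=0)
    src0, tgt0 = src - src_c, tgt - tgt_c
    # degenerate when the source points are (near) collinear
    svals = np.linalg.svd(src0, compute_uv=False)
    if svals[1] < 1e-9 * max(svals[0], 1e-30):
        raise DomainError("tie points are collinear; rotation is not unique")
    rot, _ = Rotation.align_vectors(tgt0, src0)
    rotation = rot.as_matrix()
    translation = tgt_c - rotation @ src_c
    transform = RigidTransform(rotation, translation)
    residuals = np.linalg.norm(transform.apply(src) - tgt, axis=1)
    return RegistrationReport(transform=transform, residuals=residuals)


def merge_clouds(clouds: list[PointCloud]) -> PointCloud:
    """Concatenate clouds (all in one frame), tagging each point's source.

    A ``source`` attribute records the list index a point came from;
    existing ``source`` attributes are preserved.  Other attributes are
    kept when present in every input cloud.
    """
    if not clouds:
        raise DomainError("merge_clouds needs at least one cloud")
    xyz = np.vstack([c.xyz for c in clouds])
    shared = set(clouds[0].attributes)
    for c in clouds[1:]:
        shared &= set(c.attributes)
    attributes = {
        name: np.concatenate([c.attributes[name] for c in clouds])
        for name in shared
        if name != "source"
    }
    if all("source" in c.attributes for c in clouds):
        attributes["source"] = np.concatenate([c.attributes["source"] for c in clouds])
    else:
        attributes["source"] = np.concatenate(
            [np.full(len(c), i, dtype=int) for i, c in enumerate(clouds)]
        )
    return PointCloud(xyz, attributes)


def crop_to_aoi(
    cloud: PointCloud, xmin: float, ymin: float, xmax: float, ymax: float
) -> PointCloud:
    """Keep points inside the closed axis-aligned area of interest."""
    if not (xmin < xmax and ymin < ymax):
        raise DomainError("inverted AOI bounds")
    keep = (
        (cloud.x >= xmin)
        & (cloud.x <= xmax)
        & (cloud.y >= ymin)
        & (cloud.y <= ymax)
    )
    return cloud.select(keep)


def read_tiepoints_csv(path) -> TiePointSet:
    """Read tie points from a 6-column CSV (xs, ys, zs, xt, yt, zt), header required."""
    table = pd.read_csv(path)
    required = ["xs", "ys", "zs", "xt", "yt", "zt"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise DomainError(f"tie point CSV lacks columns: {missing}")
    return TiePointSet(
        source=table[["xs", "ys", "zs"]].to_numpy(float),
        target=table[["xt", "yt", "zt"]].to_numpy(float),
    )


def retention_percent(n_final: int, n_original: int) -> float:
    """Share of an original point cloud surviving pre-processing, in percent."""
    if n_original <= 0:
        raise DomainError("original point count must be positive")
    return 100.0 * n_final / n_original
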