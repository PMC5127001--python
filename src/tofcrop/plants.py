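"""Individual plant height extraction and paired height comparison.

Two extraction scenarios, matching how the point clouds may be used in
the field:

* **Scenario 1** — no georeference, no prior knowledge: canopy-surface
  local maxima stand in for plant positions; each plant height is the
  local maximum minus the lowest point within a small horizontal search
  radius, and implausibly small values (below the known minimum plant
  height) are discarded.
* **Scenario 2** — plant positions known (e.g. from an early-season
  survey): heights are the z range of the points within the search
  radius around each known position.

Heights from a test sensor are compared against a reference cloud by
matching to the nearest reference local maximum within the same radius,
then summarised by an OLS fit (R^2) and by the median, SD and RMSE of
the height differences (test - reference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .geometry import DomainError, PointCloud

__all__ = [
    "PlantObservation",
    "HeightPairSet",
    "find_local_maxima",
    "heights_scenario1",
    "heights_scenario2",
    "match_to_reference",
    "compare_heights",
]

DEFAULT_RADIUS = 0.125
DEFAULT_MIN_HEIGHT = 0.500


@dataclass
class PlantObservation:
    """One extracted plant height observation.

    A missing observation (scenario 2 position with an empty search
    disc) carries NaN for ``z_max``/``z_min``/``height``.
    """

    position: tuple[float, float]
    z_max: float
    z_min: float
    height: float
    source: str = ""

    @property
    def valid(self) -> bool:
        return bool(np.isfinite(self.height))


@dataclass
class HeightPairSet:
    """Paired test/reference heights with fit and difference statistics."""

    pairs: np.ndarray  # (n, 2): test, reference
    slope: float
    intercept: float
    r2: float
    median: float
    sd: float
    rmse: float
    n_unmatched: int = 0

    @property
    def n(self) -> int:
        return len(self.pairs)

    @property
    def differences(self) -> np.ndarray:
        return self.pairs[:, 0] - self.pairs[:, 1]


def _local_maxima_mask(xyz: np.ndarray, radius: float) -> np.ndarray:
    """Boolean mask of points strictly highest within their horizontal disc.

    Ties are broken by index: of several equally high points within one
    radius, only the first is a maximum.  A coarse-grid prefilter keeps
    the exact disc check to a few candidates per cell: with cell size
    radius/sqrt(2) any point that is not its cell's running maximum has
    a higher-or-earlier point within ``radius`` (the cell diagonal), so
    only per-cell maxima need the exact test.
    """
    n = len(xyz)
    xy, z = xyz[:, :2], xyz[:, 2]
    cell = radius / math.sqrt(2.0)
    ij = np.floor(xy / cell).astype(np.int64)
    # order: by cell, then z descending, then index ascending -> first row
    # per cell is the cell's maximum under the tie rule
    order = np.lexsort((np.arange(n), -z, ij[:, 1], ij[:, 0]))
    sorted_ij = ij[order]
    first = np.ones(n, dtype=bool)
    if n > 1:
        first[1:] = np.any(sorted_ij[1:] != sorted_ij[:-1], axis=1)
    candidates = order[first]

    tree = cKDTree(xy)
    mask = np.zeros(n, dtype=bool)
    for i in candidates:
        neighbours = tree.query_ball_point(xy[i], radius)
        zi = z[i]
        is_max = True
        for j in neighbours:
            if j == i:
                continue
            if z[j] > zi or (z[j] == zi and j < i):
                is_max = False
                break
        mask[i] = is_max
    return mask


def find_local_maxima(cloud: PointCloud, radius: float = DEFAULT_RADIUS) -> PointCloud:
    """Points that are the strictly highest within their horizontal disc.

    The neighbourhood is two-dimensional (x, y); ties are broken in
    favour of the lowest point index.
    """
    if radius <= 0:
        raise DomainError("radius must be positive")
    if len(cloud) == 0:
        raise DomainError("cannot search an empty cloud for maxima")
    mask = _local_maxima_mask(cloud.xyz, radius)
    out = cloud.select(mask)
    out.attributes["index"] = np.flatnonzero(mask)
    return out


def heights_scenario1(
    cloud: PointCloud,
    radius: float = DEFAULT_RADIUS,
    min_height: float = DEFAULT_MIN_HEIGHT,
) -> list[PlantObservation]:
    """Plant heights without known positions (scenario 1).

    For each canopy local maximum the lowest point within the horizontal
    search radius is extracted; the height is their z difference.
    Heights below ``min_height`` are excluded (a priori knowledge that
    every plant in the plot is taller).
    """
    maxima = find_local_maxima(cloud, radius)
    tree = cKDTree(cloud.xyz[:, :2])
    observations = []
    for k in range(len(maxima)):
        x, y, z_max = maxima.xyz[k]
        idx = tree.query_ball_point((x, y), radius)
        z_min = float(cloud.z[idx].min())
        height = z_max - z_min
        if height < min_height:
            continue
        observations.append(
            PlantObservation(
                position=(float(x), float(y)),
                z_max=float(z_max),
                z_min=z_min,
                height=float(height),
                source="scenario1",
            )
        )
    return observations


def heights_scenario2(
    cloud: PointCloud,
    positions,
    radius: float = DEFAULT_RADIUS,
) -> list[PlantObservation]:
    """Plant heights at known positions (scenario 2).

    For each (x, y) position the height is the z range of the points in
    the horizontal disc of ``radius``; empty discs yield a
    missing-observation marker (NaN height) rather than being dropped.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    if len(positions) == 0:
        raise DomainError("scenario 2 needs at least one known position")
    tree = cKDTree(cloud.xyz[:, :2]) if len(cloud) else None
    observations = []
    for x, y in positions:
        idx = tree.query_ball_point((x, y), radius) if tree is not None else []
        if idx:
            z = cloud.z[idx]
            z_max, z_min = float(z.max()), float(z.min())
            height = z_max - z_min
        else:
            z_max = z_min = height = float("nan")
        observations.append(
            PlantObservation(
                position=(float(x), float(y)),
                z_max=z_max,
                z_min=z_min,
                height=height,
                source="scenario2",
            )
        )
    return observations


def match_to_reference(
    observations: list[PlantObservation],
    ref_cloud: PointCloud,
    radius: float = DEFAULT_RADIUS,
    min_height: float = DEFAULT_MIN_HEIGHT,
) -> tuple[np.ndarray, int]:
    """Pair test observations with reference-cloud plant heights.

    Reference heights are extracted from ``ref_cloud`` with the same
    local-maximum procedure (scenario 1); each valid test observation is
    paired with the nearest reference maximum within the horizontal
    ``radius``.  Returns ``(pairs, n_unmatched)`` where ``pairs`` is an
    (n, 2) array of (test height, reference height); unmatched
    observations are dropped but counted.
    """
    ref_obs = [o for o in heights_scenario1(ref_cloud, radius, min_height) if o.valid]
    if not ref_obs:
        return np.empty((0, 2)), sum(1 for o in observations if o.valid)
    ref_xy = np.array([o.position for o in ref_obs])
    ref_h = np.array([o.height for o in ref_obs])
    tree = cKDTree(ref_xy)
    pairs = []
    unmatched = 0
    for obs in observations:
        if not obs.valid:
            continue
        dist, j = tree.query(obs.position, k=1)
        if dist <= radius:
            pairs.append((obs.height, ref_h[j]))
        else:
            unmatched += 1
    return np.asarray(pairs, dtype=float).reshape(-1, 2), unmatched


def compare_heights(pairs: np.ndarray, n_unmatched: int = 0) -> HeightPairSet:
    """Summarise paired (test, reference) heights.

    Fits test = slope * reference + intercept by ordinary least squares
    and reports R^2 together with the median, standard deviation and
    RMSE of the differences (test - reference).
    """
    pairs = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if len(pairs) < 2:
        raise DomainError("height comparison needs at least 2 pairs")
    test, ref = pairs[:, 0], pairs[:, 1]
    if np.ptp(ref) == 0 or np.ptp(test) == 0:
        slope, intercept = (0.0, float(np.mean(test)))
        r2 = 1.0 if np.allclose(test - ref, (test - ref)[0]) else 0.0
    else:
        fit = stats.linregress(ref, test)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    diff = test - ref
    return HeightPairSet(
        pairs=pairs,
        slope=slope,
        intercept=intercept,
        r2=r2,
        median=float(np.median(diff)),
        sd=float(np.std(diff, ddof=1)),
        rmse=float(np.sqrt(np.mean(diff**2))),
        n_unmatched=n_unmatched,
    )
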