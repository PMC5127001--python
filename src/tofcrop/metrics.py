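"""Accuracy assessment of height models and sensor characterisation.

The raster accuracy suite follows robust DEM assessment practice:
alongside RMSE, mean and SD it reports
statistics that are insensitive to blunders (gross errors) — the signed
median, the 68.3 % and 95 % quantiles of the absolute differences, and
the normalised median absolute deviation

    NMAD = 1.4826 * median(|dh_i - median(dh)|),

a consistent estimator of sigma under normality.  Blunders are defined
as differences whose absolute value exceeds three times the RMSE.

Sensor characterisation covers the precision/accuracy of a depth camera
from repeated scans of a planar target (inner third of the frame only,
to stay clear of lens distortion at the frame edges) and the statistics
of measurement artefacts — spurious points in an empty scene, which
concentrate on the faces of the viewing frustum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chm import RasterGrid
from .geometry import (
    DomainError,
    FrustumSpec,
    PointCloud,
    SensorPose,
    fit_plane_ransac,
    frustum_face_distances,
)

__all__ = [
    "AccuracyReport",
    "ArtefactStats",
    "SensorPerformance",
    "nmad",
    "accuracy_report",
    "cellwise_fit",
    "plane_precision_accuracy",
    "aggregate_performance",
    "artefact_stats",
]

NMAD_CONSTANT = 1.4826
BLUNDER_FACTOR = 3.0


@dataclass
class AccuracyReport:
    """Difference-raster statistics (all length quantities in metres)."""

    rmse: float
    mean: float
    sd: float
    mean_no_blunder: float
    sd_no_blunder: float
    q50: float  # signed median of the differences
    q683: float  # 68.3 % quantile of |differences|
    q95: float  # 95 % quantile of |differences|
    nmad: float
    qq_r2: float  # NaN when undefined (zero spread)
    blunder_count: int
    n_cells: int
    cell_r2: float = float("nan")
    cell_slope: float = float("nan")
    cell_intercept: float = float("nan")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class ArtefactStats:
    """Counts and FOV-boundary distance statistics of measurement artefacts."""

    count_mean: float
    count_sd: float
    dist_median: float
    dist_max: float
    dist_sd: float


@dataclass
class SensorPerformance:
    """Precision/accuracy of a depth sensor at one nominal range."""

    nominal_range: float
    precision: float  # SD of residuals to the fitted plane
    accuracy_rmse: float  # RMS of |mean measured range - nominal| over repeats


def nmad(differences) -> float:
    """Normalised median absolute deviation about the median."""
    diff = np.asarray(differences, dtype=float).ravel()
    if diff.size == 0:
        raise DomainError("NMAD of an empty sample is undefined")
    med = np.median(diff)
    return float(NMAD_CONSTANT * np.median(np.abs(diff - med)))


def _qq_r2(diff: np.ndarray) -> float:
    """Squared Pearson correlation of the normal Q-Q scatter.

    Sorted standardised differences against standard-normal quantiles at
    the (i - 0.5)/n plotting positions; NaN when the sample has zero
    spread (the Q-Q plot degenerates to a horizontal line).
    """
    sd = diff.std(ddof=1)
    if np.ptp(diff) == 0 or len(diff) < 2:
        return float("nan")
    standardized = np.sort((diff - diff.mean()) / sd)
    n = len(diff)
    theoretical = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    r = np.corrcoef(theoretical, standardized)[0, 1]
    return float(r**2)


def accuracy_report(
    diff: RasterGrid | np.ndarray, blunder_factor: float = BLUNDER_FACTOR
) -> AccuracyReport:
    """Full accuracy statistics of a difference raster (or 1D sample).

    Quantiles use linear interpolation between order statistics; q683
    and q95 are quantiles of the absolute differences, q50 is the signed
    median.  Blunders (|dh| > blunder_factor * RMSE) are excluded from
    the ``*_no_blunder`` mean and SD.
    """
    if isinstance(diff, RasterGrid):
        values = diff.valid_values()
    else:
        values = np.asarray(diff, dtype=float).ravel()
        values = values[np.isfinite(values)]
    if values.size < 2:
        raise DomainError("accuracy report needs at least 2 valid cells")

    rmse = float(np.sqrt(np.mean(values**2)))
    absolute = np.abs(values)
    blunder = absolute > blunder_factor * rmse
    clean = values[~blunder]
    return AccuracyReport(
        rmse=rmse,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        mean_no_blunder=float(clean.mean()) if clean.size else float("nan"),
        sd_no_blunder=float(clean.std(ddof=1)) if clean.size > 1 else 0.0,
        q50=float(np.median(values)),
        q683=float(np.quantile(absolute, 0.683)),
        q95=float(np.quantile(absolute, 0.95)),
        nmad=nmad(values),
        qq_r2=_qq_r2(values),
        blunder_count=int(blunder.sum()),
        n_cells=int(values.size),
    )


def cellwise_fit(test: RasterGrid, reference: RasterGrid) -> tuple[float, float, float]:
    """OLS of test on reference over co-valid cells: (r2, slope, intercept)."""
    if not test.aligned_with(reference):
        raise DomainError("cellwise fit requires aligned grids")
    mask = test.valid_mask & reference.valid_mask
    if mask.sum() < 2:
        raise DomainError("cellwise fit needs at least 2 co-valid cells")
    x = reference.values[mask]
    y = test.values[mask]
    if np.ptp(x) == 0:
        raise DomainError("reference values are constant; fit is undefined")
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2), float(fit.slope), float(fit.intercept)


def plane_precision_accuracy(
    clouds: PointCloud | list[PointCloud],
    nominal_range: float,
    spec: FrustumSpec = FrustumSpec(),
    center_fraction: float = 1.0 / 3.0,
    dist_threshold: float = 0.02,
    seed: int = 0,
) -> SensorPerformance:
    """Precision and accuracy from scans of a plane facing the sensor.

    Clouds must be in the sensor frame (z = depth).  Each scan is
    cropped to the central ``center_fraction`` of the field of view,
    a plane is fitted by RANSAC, and

    * precision = SD of the residual distances to the plane (pooled
      over repeats),
    * accuracy  = RMS over repeats of (mean measured depth - nominal).
    """
    if isinstance(clouds, PointCloud):
        clouds = [clouds]
    if not clouds:
        raise DomainError("need at least one scan")
    residual_sq, mean_errors, n_res = 0.0, [], 0
    for cloud in clouds:
        z = cloud.z
        keep = (np.abs(cloud.x) <= center_fraction * z * spec.tan_h) & (
            np.abs(cloud.y) <= center_fraction * z * spec.tan_v
        )
        inner = cloud.select(keep)
        if len(inner) < 3:
            raise DomainError("too few points in the central field of view")
        plane = fit_plane_ransac(inner, dist_threshold=dist_threshold, seed=seed)
        res = plane.residuals(inner.xyz)
        residual_sq += float(np.sum((res - res.mean()) ** 2))
        n_res += len(res)
        mean_errors.append(float(inner.z.mean()) - nominal_range)
    precision = float(np.sqrt(residual_sq / max(n_res - 1, 1)))
    accuracy = float(np.sqrt(np.mean(np.square(mean_errors))))
    return SensorPerformance(
        nominal_range=nominal_range, precision=precision, accuracy_rmse=accuracy
    )


def aggregate_performance(records: list[SensorPerformance]) -> dict:
    """Summary of per-range performance records (ranges must be distinct)."""
    records = sorted(records, key=lambda r: r.nominal_range)
    return {
        "ranges": [r.nominal_range for r in records],
        "precision": [r.precision for r in records],
        "accuracy_rmse": [r.accuracy_rmse for r in records],
    }


def artefact_stats(
    frames: list[PointCloud], pose: SensorPose, spec: FrustumSpec
) -> ArtefactStats:
    """Artefact counts and FOV-boundary distances from empty-scene frames.

    Every point in a frame of an empty scene is a measurement artefact.
    Counts are summarised per frame (mean, SD); distances of all points
    to the frustum boundary are pooled for the median/max/SD.
    """
    if not frames:
        raise DomainError("artefact statistics need at least one frame")
    counts = np.array([len(f) for f in frames], dtype=float)
    all_points = [f.xyz for f in frames if len(f)]
    if all_points:
        pooled = PointCloud(np.vstack(all_points))
        d = frustum_face_distances(pooled, pose, spec)
        dist_median, dist_max, dist_sd = (
            float(np.median(d)),
            float(d.max()),
            float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        )
    else:
        dist_median = dist_max = dist_sd = float("nan")
    return ArtefactStats(
        count_mean=float(counts.mean()),
        count_sd=float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
        dist_median=dist_median,
        dist_max=dist_max,
        dist_sd=dist_sd,
    )
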