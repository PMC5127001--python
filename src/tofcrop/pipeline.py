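"""End-to-end workflow: campaign -> pre-processing -> CHMs -> assessment.

Ties the stage modules together in the method's fixed order.  Each depth
frame is clipped to the field of view at its canopy-top range, cropped
to the area of interest and cleaned with statistical outlier removal;
the cleaned clouds are rasterised into DSM/DTM/CHM per single frame and
for the frame combinations 1-3-5-7, 2-4-6-8 and all frames, and every
crop height model is assessed against the reference-scanner CHM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chm import CHMSet, build_chm_set, difference_raster, grid_definition_for_aoi
from .geometry import FrustumSpec, PointCloud, SensorPose, clip_to_top_fov
from .io import PipelineConfig
from .metrics import AccuracyReport, accuracy_report, cellwise_fit
from .plants import compare_heights, heights_scenario1, heights_scenario2, match_to_reference
from .preprocess import crop_to_aoi, merge_clouds, retention_percent, sor_filter
from .synth import Campaign, SyntheticField

__all__ = [
    "FrameResult",
    "top_range_for_frame",
    "preprocess_frame",
    "assess_chm",
    "run_campaign_analysis",
    "CampaignAnalysis",
]

#: Frame combinations evaluated alongside the single frames (0-based indices).
DEFAULT_COMBINATIONS: dict[str, tuple[int, ...]] = {
    "1-3-5-7": (0, 2, 4, 6),
    "2-4-6-8": (1, 3, 5, 7),
    "all": (0, 1, 2, 3, 4, 5, 6, 7),
}


@dataclass
class FrameResult:
    """Pre-processing outcome of one depth frame."""

    cloud: PointCloud
    n_original: int
    n_clipped: int
    n_final: int

    @property
    def retention(self) -> float:
        return retention_percent(self.n_final, self.n_original)


def top_range_for_frame(
    pose: SensorPose, field: SyntheticField, spec: FrustumSpec
) -> float:
    """Sensor-to-highest-plant depth for the plants visible in a frame.

    The highest plant "within the measured scene" is the tallest plant
    whose stem falls inside the FOV cross-section at its own apex depth.
    Falls back to the terrain depth (clamped to the range limits) when
    the frame sees no plants.
    """
    apex_world = np.column_stack(
        [
            field.positions(),
            field.terrain_z(field.positions()[:, 0], field.positions()[:, 1])
            + field.truth_heights(),
        ]
    )
    if len(apex_world):
        s = pose.to_sensor(apex_world)
        depth = s[:, 2]
        visible = (
            (depth > 0)
            & (np.abs(s[:, 0]) <= depth * spec.tan_h)
            & (np.abs(s[:, 1]) <= depth * spec.tan_v)
        )
        if visible.any():
            return float(
                np.clip(depth[visible].min(), spec.min_range, spec.max_range)
            )
    ground_depth = pose.to_sensor(
        np.array([[pose.origin[0], pose.origin[1], field.terrain_z(*pose.origin[:2])]])
    )[0, 2]
    return float(np.clip(ground_depth, spec.min_range, spec.max_range))


def preprocess_frame(
    cloud: PointCloud,
    pose: SensorPose,
    top_range: float,
    config: PipelineConfig,
) -> FrameResult:
    """Clip to the canopy-top FOV, crop to the AOI, remove outliers."""
    n_original = len(cloud)
    clipped = clip_to_top_fov(cloud, pose, config.frustum, top_range)
    cropped = crop_to_aoi(clipped, *config.aoi)
    kept, _ = sor_filter(
        cropped, k=config.sor_k, multiplier=config.sor_multiplier,
        literal=config.sor_literal,
    )
    return FrameResult(
        cloud=kept, n_original=n_original, n_clipped=len(clipped), n_final=len(kept)
    )


def assess_chm(test: CHMSet, reference: CHMSet, config: PipelineConfig) -> AccuracyReport:
    """Difference-raster statistics plus the cell-level fit of a CHM pair."""
    diff = difference_raster(test.chm, reference.chm)
    report = accuracy_report(diff, blunder_factor=config.blunder_factor)
    try:
        report.cell_r2, report.cell_slope, report.cell_intercept = cellwise_fit(
            test.chm, reference.chm
        )
    except Exception:
        pass  # too few co-valid cells: cell fit stays NaN
    return report


@dataclass
class CampaignAnalysis:
    """Everything the campaign workflow produces."""

    frame_results: list[FrameResult]
    chm_variants: dict[str, CHMSet]
    reference_chm: CHMSet
    reports: pd.DataFrame
    plant_scenario2: dict[str, object]
    plant_scenario2_single: dict[str, object]
    plant_scenario1: dict[str, object]
    retention: pd.DataFrame


def run_campaign_analysis(
    campaign: Campaign, config: PipelineConfig | None = None
) -> CampaignAnalysis:
    """Run the full height-model workflow on a rendered campaign.

    Produces the 11 CHM variants (8 single frames, 1-3-5-7, 2-4-6-8,
    all), their accuracy reports against the reference CHM, and
    individual plant heights for both scenarios (known positions, and
    local-maxima extraction matched to the reference cloud).
    """
    config = config or PipelineConfig()
    field = campaign.field
    origin, shape = grid_definition_for_aoi(*config.aoi, config.cell_size)

    frame_results = []
    for frame, pose in zip(campaign.k2_frames, campaign.k2_poses):
        top = top_range_for_frame(pose, field, campaign.spec)
        frame_results.append(preprocess_frame(frame, pose, top, config))

    tls_cropped = crop_to_aoi(campaign.tls_reference, *config.aoi)
    tls_clean, _ = sor_filter(
        tls_cropped, k=config.sor_k, multiplier=config.sor_multiplier,
        literal=config.sor_literal,
    )
    reference_chm = build_chm_set(
        tls_clean, origin, config.cell_size, shape, config.trim_rings
    )

    variants: dict[str, PointCloud] = {
        f"SP{i + 1}": r.cloud for i, r in enumerate(frame_results)
    }
    n = len(frame_results)
    for name, idx in DEFAULT_COMBINATIONS.items():
        members = [frame_results[i].cloud for i in idx if i < n]
        if members:
            variants[name] = merge_clouds(members)

    chm_variants: dict[str, CHMSet] = {}
    rows = []
    for name, cloud in variants.items():
        chm_set = build_chm_set(cloud, origin, config.cell_size, shape, config.trim_rings)
        chm_variants[name] = chm_set
        report = assess_chm(chm_set, reference_chm, config)
        rows.append({"variant": name, **report.as_dict()})
    reports = pd.DataFrame(rows)

    combined = variants["all"]
    positions = field.positions()
    truth = field.truth_heights()

    # scenario 2: known positions, combined cloud, against ground truth
    obs2 = heights_scenario2(combined, positions, config.plant_radius)
    valid2 = np.array([o.valid for o in obs2])
    heights2 = np.array([o.height for o in obs2])
    pairs2 = np.column_stack([heights2[valid2], truth[valid2]])
    scenario2 = {
        "observations": obs2,
        "comparison": compare_heights(pairs2) if len(pairs2) >= 2 else None,
        "n_missing": int((~valid2).sum()),
    }

    # scenario 2 on each single frame, pooled: one plant can be observed in
    # several frames, so the pool can exceed the plant count
    single_pairs = []
    for result in frame_results:
        if len(result.cloud) == 0:
            continue
        obs = heights_scenario2(result.cloud, positions, config.plant_radius)
        for o, h_true in zip(obs, truth):
            if o.valid:
                single_pairs.append((o.height, h_true))
    single_pairs = np.asarray(single_pairs, dtype=float).reshape(-1, 2)
    scenario2_single = {
        "pairs": single_pairs,
        "comparison": compare_heights(single_pairs) if len(single_pairs) >= 2 else None,
    }

    # scenario 1: local maxima on the combined cloud, matched to the TLS cloud
    obs1 = heights_scenario1(combined, config.plant_radius, config.min_plant_height)
    pairs1, unmatched = match_to_reference(
        obs1, tls_clean, config.plant_radius, config.min_plant_height
    )
    scenario1 = {
        "observations": obs1,
        "comparison": compare_heights(pairs1, unmatched) if len(pairs1) >= 2 else None,
        "n_unmatched": unmatched,
    }

    retention = pd.DataFrame(
        [
            {
                "frame": f"SP{i + 1}",
                "original": r.n_original,
                "clipped": r.n_clipped,
                "final": r.n_final,
                "retention_percent": r.retention,
            }
            for i, r in enumerate(frame_results)
        ]
    )
    return CampaignAnalysis(
        frame_results=frame_results,
        chm_variants=chm_variants,
        reference_chm=reference_chm,
        reports=reports,
        plant_scenario2=scenario2,
        plant_scenario2_single=scenario2_single,
        plant_scenario1=scenario1,
        retention=retention,
    )
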