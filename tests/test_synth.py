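"""Virtual field, depth-camera and laser-scanner rendering."""

import math

import numpy as np
import pytest

from tofcrop.chm import build_chm_set, grid_definition_for_aoi
from tofcrop.geometry import FrustumSpec, PointCloud, SensorPose
from tofcrop.plants import heights_scenario2
from tofcrop.preprocess import crop_to_aoi, merge_clouds
from tofcrop.synth import (
    ArtefactModel,
    NoiseModel,
    PlantShape,
    generate_field,
    render_depth_frame,
    render_tls_scan,
)

SPEC = FrustumSpec()


class TestGenerateField:
    def test_default_layout(self):
        field = generate_field(seed=3)
        assert field.n_plants == 52
        xy = field.positions()
        assert np.all((xy[:, 0] >= 0) & (xy[:, 0] <= 2.5))
        assert np.all((xy[:, 1] >= 0) & (xy[:, 1] <= 8.0))
        h = field.truth_heights()
        assert h.min() >= 0.55 and h.max() <= 2.41

    def test_mean_spacings_within_five_percent(self):
        field = generate_field(seed=3)
        table = field.plants.assign(
            col=np.round((field.plants.x - field.plants.x.min()) / 0.46).astype(int),
            row=np.round((field.plants.y - field.plants.y.min()) / 0.58).astype(int),
        )
        long_gaps = [
            np.diff(np.sort(g.y.values)).mean()
            for _, g in table.groupby("col")
            if len(g) > 1
        ]
        trans_gaps = [
            np.diff(np.sort(g.x.values)).mean()
            for _, g in table.groupby("row")
            if len(g) > 1
        ]
        assert np.mean(long_gaps) == pytest.approx(0.58, rel=0.05)
        assert np.mean(trans_gaps) == pytest.approx(0.46, rel=0.05)

    def test_height_gradient_increases_along_y(self):
        field = generate_field(seed=3)
        south = field.plants.nsmallest(10, "y").height.mean()
        north = field.plants.nlargest(10, "y").height.mean()
        assert north > south + 1.0

    def test_single_plant_at_plot_centre(self):
        field = generate_field(n_plants=1, position_jitter_sd=0.0, seed=0)
        assert np.allclose(field.positions()[0], [1.25, 4.0])

    def test_seed_determinism(self):
        a = generate_field(seed=11)
        b = generate_field(seed=11)
        c = generate_field(seed=12)
        assert a.plants.equals(b.plants)
        assert not a.plants.equals(c.plants)


class TestDepthFrame:
    def test_bare_plane_returns_every_pixel_with_closed_form_ranges(self):
        field = generate_field(n_plants=0, seed=0)
        pose = SensorPose.nadir(origin=(0.0, 0.0, 3.75))
        frame = render_depth_frame(field, pose, SPEC, noise=None, artefacts=None)
        assert len(frame) == 217_088
        # per-pixel closed form: depth 3.75, Euclidean range 3.75 / cos(theta)
        assert np.allclose(3.75 - frame.z, 3.75, atol=1e-9)
        ranges = np.linalg.norm(frame.xyz - pose.origin, axis=1)
        u = ((np.arange(SPEC.n_cols) + 0.5) / SPEC.n_cols - 0.5) * 2 * SPEC.tan_h
        v = ((np.arange(SPEC.n_rows) + 0.5) / SPEC.n_rows - 0.5) * 2 * SPEC.tan_v
        uu, vv = np.meshgrid(u, v)
        cos_theta = 1.0 / np.sqrt(1.0 + uu.ravel() ** 2 + vv.ravel() ** 2)
        assert np.allclose(np.sort(ranges), np.sort(3.75 / cos_theta), atol=1e-9)

    def test_out_of_range_plane_returns_nothing(self):
        field = generate_field(n_plants=0, seed=0)
        pose = SensorPose.nadir(origin=(0.0, 0.0, 6.0))  # beyond max_range
        frame = render_depth_frame(field, pose, SPEC)
        assert len(frame) == 0

    def test_plant_occludes_terrain_against_bruteforce_raycast(self, rng):
        field = generate_field(
            n_plants=1, extent=(2.0, 2.0), height_range=(1.8, 1.8),
            position_jitter_sd=0.0, height_jitter_sd=0.0, seed=5,
        )
        pose = SensorPose.nadir(origin=(1.0, 1.0, 3.0))
        frame = render_depth_frame(field, pose, SPEC, noise=None, artefacts=None)
        # brute-force scalar ray cast over all triangles on a pixel subset
        tris = np.vstack(
            [t for _, parts in field.meshes() for t, _ in parts]
        )
        dirs = (frame.xyz - pose.origin) / np.maximum(
            (pose.origin[2] - frame.z)[:, None], 1e-12
        )
        pick = rng.choice(len(frame), 150, replace=False)
        for i in pick:
            t_expected = 3.0  # terrain
            o, d = pose.origin, dirs[i]
            for v0, v1, v2 in tris:
                e1, e2 = v1 - v0, v2 - v0
                h = np.cross(d, e2)
                a = e1 @ h
                if abs(a) < 1e-12:
                    continue
                f = 1.0 / a
                s = o - v0
                u = f * (s @ h)
                if u < -1e-9 or u > 1 + 1e-9:
                    continue
                q = np.cross(s, e1)
                v = f * (d @ q)
                if v < -1e-9 or u + v > 1 + 1e-9:
                    continue
                t = f * (e2 @ q)
                if 1e-9 < t < t_expected:
                    t_expected = t
            depth_rendered = pose.origin[2] - frame.z[i]
            assert depth_rendered == pytest.approx(t_expected, abs=1e-9)

    def test_render_is_bitwise_reproducible(self):
        field = generate_field(n_plants=4, extent=(2.0, 2.0), seed=7)
        pose = SensorPose.nadir(origin=(1.0, 1.0, 3.75))
        a = render_depth_frame(field, pose, SPEC, NoiseModel(),
                               ArtefactModel.from_lighting("night"), seed=9)
        b = render_depth_frame(field, pose, SPEC, NoiseModel(),
                               ArtefactModel.from_lighting("night"), seed=9)
        assert np.array_equal(a.xyz, b.xyz)
        assert np.array_equal(a.attributes["artefact"], b.attributes["artefact"])

    def test_finer_tips_increase_height_underestimation(self):
        """Coarser apices are easier for the pixel grid to sample, so the
        plant-height bias magnitude shrinks as tip_radius grows."""
        base = generate_field(
            n_plants=4, extent=(2.0, 2.0), spacing=(0.8, 0.8),
            height_range=(1.7, 2.2), seed=21,
        )
        pose = SensorPose.nadir(origin=(1.0, 1.0, 3.75))
        biases = []
        for tip in (0.0015, 0.004, 0.012):
            field = base.with_shape(PlantShape(tip_radius=tip))
            frame = render_depth_frame(field, pose, SPEC, noise=None, artefacts=None)
            obs = heights_scenario2(frame, field.positions())
            err = [o.height - h for o, h in zip(obs, field.truth_heights()) if o.valid]
            biases.append(abs(np.median(err)))
        assert biases[0] >= biases[1] >= biases[2]
        assert biases[0] > biases[2]


class TestTlsScan:
    def test_point_spacing_at_five_metres(self):
        spacing = 2 * 5.0 * math.tan(math.radians(0.029) / 2)
        assert round(spacing, 4) == 0.0025

    def test_flat_terrain_returns_exact_ground(self):
        field = generate_field(n_plants=0, seed=0)
        cloud = render_tls_scan(
            field, (-1.0, -1.0, 3.5), angular_resolution=0.5, range_noise_sd=0.0
        )
        assert len(cloud) > 100
        assert np.max(np.abs(cloud.z)) < 1e-9

    def test_scan_is_reproducible(self):
        field = generate_field(n_plants=3, extent=(2.0, 2.0), seed=2)
        a = render_tls_scan(field, (-1.0, -1.0, 3.5), 0.4, seed=5)
        b = render_tls_scan(field, (-1.0, -1.0, 3.5), 0.4, seed=5)
        assert np.array_equal(a.xyz, b.xyz)


class TestCampaign:
    def test_poses_span_long_axis_monotonically(self, campaign_bundle):
        field, campaign, _ = campaign_bundle
        ys = [p.origin[1] for p in campaign.k2_poses]
        assert all(b > a for a, b in zip(ys, ys[1:]))
        assert ys[0] <= 1.0 and ys[-1] >= 7.0

    def test_merged_frames_cover_aoi_without_empty_cells(self, campaign_bundle):
        field, campaign, _ = campaign_bundle
        merged = crop_to_aoi(merge_clouds(campaign.k2_frames), 0, 0, 2.5, 8.0)
        origin, shape = grid_definition_for_aoi(0, 0, 2.5, 8.0, 0.25)
        chm = build_chm_set(merged, origin, 0.25, shape, trim_rings=0)
        assert chm.dsm.n_valid == shape[0] * shape[1]

    def test_tls_merge_covers_ground_completely(self, campaign_bundle):
        """5 scanner positions leave no empty terrain cell in the
        reference DTM (inside the trimmed analysis extent)."""
        field, campaign, analysis = campaign_bundle
        dtm = analysis.reference_chm.dtm
        assert dtm.n_valid == dtm.values.size

    def test_bare_terrain_pipeline_chm_error_is_zero(self):
        """With noise and artefacts off the CHM is exact on bare terrain."""
        field = generate_field(n_plants=0, extent=(2.0, 2.0), seed=1)
        pose = SensorPose.nadir(origin=(1.0, 1.0, 3.0))
        frame = render_depth_frame(field, pose, SPEC, noise=None, artefacts=None)
        origin, shape = grid_definition_for_aoi(0, 0, 2.0, 2.0, 0.25)
        chm = build_chm_set(crop_to_aoi(frame, 0, 0, 2, 2), origin, 0.25, shape, 0)
        assert np.max(np.abs(chm.chm.valid_values())) <= 1e-12
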