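"""Robust accuracy statistics and sensor characterisation."""

import math

import numpy as np
import pytest

from tofcrop.chm import RasterGrid
from tofcrop.geometry import DomainError, FrustumSpec, PointCloud, SensorPose
from tofcrop.metrics import (
    accuracy_report,
    artefact_stats,
    cellwise_fit,
    nmad,
    plane_precision_accuracy,
)
from tofcrop.synth import ArtefactModel, NoiseModel, render_depth_frame, render_plane_target


class TestNmad:
    def test_constant_sample_is_zero(self):
        assert nmad([2.0, 2.0, 2.0]) == 0.0

    def test_unit_mad_returns_the_constant(self):
        assert nmad([1, 2, 3, 4, 5]) == pytest.approx(1.4826)

    def test_consistent_sigma_estimator_under_normality(self, rng):
        sigma = 0.7
        sample = rng.normal(0.0, sigma, 100_000)
        assert nmad(sample) == pytest.approx(sigma, rel=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(DomainError):
            nmad([])


def _naive_report(values, blunder_factor=3.0):
    """Loop/sort reimplementation of every statistic, incl. manual quantiles."""
    values = sorted(float(v) for v in values)
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    rmse = math.sqrt(sum(v * v for v in values) / n)

    def quantile(data, q):
        data = sorted(data)
        h = (len(data) - 1) * q
        lo = math.floor(h)
        hi = min(lo + 1, len(data) - 1)
        return data[lo] + (h - lo) * (data[hi] - data[lo])

    absolute = [abs(v) for v in values]
    med = quantile(values, 0.5)
    mad = quantile([abs(v - med) for v in values], 0.5)
    clean = [v for v in values if abs(v) <= blunder_factor * rmse]
    mean_nb = sum(clean) / len(clean)
    sd_nb = math.sqrt(sum((v - mean_nb) ** 2 for v in clean) / (len(clean) - 1))
    return {
        "rmse": rmse,
        "mean": mean,
        "sd": sd,
        "q50": med,
        "q683": quantile(absolute, 0.683),
        "q95": quantile(absolute, 0.95),
        "nmad": 1.4826 * mad,
        "mean_no_blunder": mean_nb,
        "sd_no_blunder": sd_nb,
        "blunder_count": n - len(clean),
    }


class TestAccuracyReport:
    def test_constant_differences(self):
        report = accuracy_report(np.full(10, -0.06))
        assert report.mean == pytest.approx(-0.06)
        assert report.q50 == pytest.approx(-0.06)
        assert report.sd == pytest.approx(0.0, abs=1e-15)
        assert report.rmse == pytest.approx(0.06)
        assert np.isnan(report.qq_r2)

    def test_all_zero_differences(self):
        report = accuracy_report(np.zeros(20))
        for name in ("rmse", "mean", "sd", "q50", "q683", "q95", "nmad"):
            assert getattr(report, name) == 0.0
        assert np.isnan(report.qq_r2)

    def test_standard_normal_sample_closed_forms(self, rng):
        sample = rng.normal(0.0, 1.0, 100_000)
        report = accuracy_report(sample)
        assert report.rmse == pytest.approx(1.0, rel=0.02)
        assert report.sd == pytest.approx(1.0, rel=0.02)
        assert report.nmad == pytest.approx(1.0, rel=0.02)
        assert report.q95 == pytest.approx(1.96, rel=0.02)
        assert report.qq_r2 > 0.99

    def test_matches_naive_reimplementation(self, rng):
        for _ in range(10):
            values = rng.normal(0, 0.1, rng.integers(10, 400))
            values[: len(values) // 10] *= 20  # gross errors
            got = accuracy_report(values)
            expected = _naive_report(values)
            for name, val in expected.items():
                assert getattr(got, name) == pytest.approx(val, abs=1e-12), name

    def test_works_on_rastergrid_with_nodata(self, rng):
        values = rng.normal(0, 0.05, (6, 8))
        values[0, :] = np.nan
        grid = RasterGrid((0, 0), 0.25, values)
        report = accuracy_report(grid)
        assert report.n_cells == 40

    def test_robust_statistics_resist_blunders(self, rng):
        base = rng.normal(0, 0.02, 500)
        contaminated = np.concatenate([base, np.full(25, 3.0)])  # 5 % blunders
        clean_r, cont_r = accuracy_report(base), accuracy_report(contaminated)
        assert cont_r.nmad == pytest.approx(clean_r.nmad, rel=0.1)
        assert abs(cont_r.q50 - clean_r.q50) < 0.005
        assert cont_r.rmse > 5 * clean_r.rmse  # RMSE/SD have no breakdown point
        assert cont_r.sd > 5 * clean_r.sd


class TestCellwiseFit:
    def test_identity(self, rng):
        grid = RasterGrid((0, 0), 0.25, rng.normal(1.5, 0.5, (5, 5)))
        r2, slope, intercept = cellwise_fit(grid, grid)
        assert (r2, slope) == (pytest.approx(1.0), pytest.approx(1.0))
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset(self, rng):
        ref = RasterGrid((0, 0), 0.25, rng.normal(1.5, 0.5, (5, 5)))
        test = RasterGrid((0, 0), 0.25, ref.values - 0.06)
        r2, slope, intercept = cellwise_fit(test, ref)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(-0.06)


class TestPlanePrecisionAccuracy:
    def test_noiseless_plane_is_perfect(self):
        cloud = render_plane_target(2.0, noise=None)
        perf = plane_precision_accuracy(cloud, 2.0)
        assert perf.precision == pytest.approx(0.0, abs=1e-9)
        assert perf.accuracy_rmse == pytest.approx(0.0, abs=1e-9)

    def test_recovers_injected_noise(self, rng):
        sigma = 0.003
        noise = NoiseModel(sd_anchors=(sigma, sigma), bias_anchors=(0.0, 0.0))
        cloud = render_plane_target(2.5, noise=noise, seed=4)
        perf = plane_precision_accuracy(cloud, 2.5, dist_threshold=5 * sigma)
        assert perf.precision == pytest.approx(sigma, rel=0.10)

    def test_default_noise_model_matches_device_characterisation(self):
        """Precision 0.001-0.003 m over the 0.8-4.0 m working range."""
        for i, r in enumerate((0.8, 1.5, 2.5, 4.0)):
            cloud = render_plane_target(r, noise=NoiseModel(), seed=10 + i)
            perf = plane_precision_accuracy(cloud, r, dist_threshold=0.02)
            assert 0.0008 <= perf.precision <= 0.0033
            # mean depth error reproduces the range-bias magnitude
            expected_bias = float(NoiseModel().bias_at(r))
            assert perf.accuracy_rmse == pytest.approx(abs(expected_bias), rel=0.25)


class TestArtefactStats:
    POSE = SensorPose.nadir(origin=(0.0, 0.0, 0.0))

    def test_empty_frames(self):
        stats = artefact_stats(
            [PointCloud(np.empty((0, 3)))] * 3, self.POSE, FrustumSpec()
        )
        assert stats.count_mean == 0.0 and stats.count_sd == 0.0

    def test_points_on_faces_have_zero_median_distance(self):
        spec = FrustumSpec()
        z = 2.0
        on_face = self.POSE.to_world(
            np.array(
                [
                    [z * spec.tan_h, 0.0, z],
                    [-z * spec.tan_h, 0.3, z],
                    [0.0, z * spec.tan_v, z],
                ]
            )
        )
        stats = artefact_stats([PointCloud(on_face)], self.POSE, spec)
        assert stats.dist_median == pytest.approx(0.0, abs=1e-9)
        assert stats.count_mean == 3.0

    def test_counts_from_injector(self):
        model = ArtefactModel(count_mean=20, count_sd=0.0)
        frames = [
            render_depth_frame(None, self.POSE, artefacts=model, seed=s)
            for s in range(5)
        ]
        stats = artefact_stats(frames, self.POSE, FrustumSpec())
        assert stats.count_mean == 20.0
        assert stats.dist_max > 0.5  # in-volume artefacts sit far from the faces
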