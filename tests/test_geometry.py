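"""Frustum model, transforms, plane fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from tofcrop.geometry import (
    DomainError,
    FrustumSpec,
    PointCloud,
    RigidTransform,
    SensorPose,
    clip_to_top_fov,
    fit_plane_ransac,
    frustum_boundary_mesh,
    frustum_contains,
    frustum_face_distances,
    theoretical_spacing,
)

NADIR = SensorPose.nadir(origin=(0.0, 0.0, 0.0))
FORWARD = SensorPose(origin=np.zeros(3), rotation=np.eye(3))  # boresight +z
SPEC = FrustumSpec()


@pytest.mark.parametrize(
    "range_m, angle, n, expected",
    [(0.5, 70, 512, 0.0014), (4.0, 70, 512, 0.0109)],
)
def test_theoretical_spacing_matches_sensor_datasheet(range_m, angle, n, expected):
    assert round(theoretical_spacing(range_m, angle, n), 4) == expected


@pytest.mark.parametrize("bad", [(0, 70, 512), (-1, 70, 512), (1, 70, 0), (1, 190, 512)])
def test_theoretical_spacing_rejects_invalid_arguments(bad):
    with pytest.raises(DomainError):
        theoretical_spacing(*bad)


@settings(derandomize=True, max_examples=50)
@given(
    r1=st.floats(0.1, 10.0),
    factor=st.floats(1.01, 5.0),
    n1=st.integers(1, 2000),
    n2=st.integers(1, 2000),
)
def test_theoretical_spacing_monotonic_in_range_and_pixels(r1, factor, n1, n2):
    assert theoretical_spacing(r1 * factor, 70, 512) > theoretical_spacing(r1, 70, 512)
    lo, hi = sorted((n1, n2))
    if lo != hi:
        assert theoretical_spacing(1.0, 70, hi) < theoretical_spacing(1.0, 70, lo)


def test_frustum_spec_validation():
    with pytest.raises(DomainError):
        FrustumSpec(h_fov=200)
    with pytest.raises(DomainError):
        FrustumSpec(min_range=2.0, max_range=1.0)
    assert SPEC.n_pixels == 512 * 424


def test_frustum_contains_boresight_and_behind():
    mid = 0.5 * (SPEC.min_range + SPEC.max_range)
    assert frustum_contains(np.array([0.0, 0.0, -mid]), NADIR, SPEC)
    assert not frustum_contains(np.array([0.0, 0.0, mid]), NADIR, SPEC)  # behind


def _oracle_contains(p, pose, spec):
    """Half-space inequalities checked one by one on a single point."""
    s = pose.rotation.T @ (np.asarray(p) - pose.origin)
    x, y, z = s
    th = math.tan(math.radians(spec.h_fov) / 2)
    tv = math.tan(math.radians(spec.v_fov) / 2)
    return (
        z >= spec.min_range
        and z <= spec.max_range
        and x <= z * th
        and -x <= z * th
        and y <= z * tv
        and -y <= z * tv
    )


def test_frustum_contains_agrees_with_halfspace_oracle(rng):
    points = rng.uniform([-6, -6, -6], [6, 6, 6], size=(1000, 3))
    got = frustum_contains(points, NADIR, SPEC)
    expected = np.array([_oracle_contains(p, NADIR, SPEC) for p in points])
    assert np.array_equal(got, expected)
    assert expected.any() and not expected.all()


def test_clip_to_top_fov_trivial_cases():
    cloud = PointCloud([[0.0, 0.0, -2.0], [3.0, 0.0, -1.5]])
    out = clip_to_top_fov(cloud, NADIR, SPEC, top_range=1.5)
    # the point directly below the sensor survives, the lateral one does not
    assert len(out) == 1 and out.xyz[0, 2] == -2.0
    with pytest.raises(DomainError):
        clip_to_top_fov(cloud, NADIR, SPEC, top_range=10.0)


def test_clip_to_top_fov_matches_bruteforce_rectangle(rng):
    points = rng.uniform([-4, -4, -5], [4, 4, 0], size=(1500, 3))
    cloud = PointCloud(points)
    top = 1.7
    out = clip_to_top_fov(cloud, NADIR, SPEC, top)
    s = NADIR.to_sensor(points)
    keep = (np.abs(s[:, 0]) <= top * math.tan(math.radians(70) / 2)) & (
        np.abs(s[:, 1]) <= top * math.tan(math.radians(60) / 2)
    )
    assert len(out) == keep.sum()
    assert np.array_equal(out.xyz, points[keep])
    # idempotent
    again = clip_to_top_fov(out, NADIR, SPEC, top)
    assert np.array_equal(again.xyz, out.xyz)


def test_rigid_transform_roundtrip_and_composition(rng):
    for _ in range(20):
        rot = Rotation.random(random_state=rng).as_matrix()
        t = RigidTransform(rot, rng.normal(size=3))
        pts = rng.normal(size=(50, 3))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)
        u = RigidTransform(Rotation.random(random_state=rng).as_matrix(), rng.normal(size=3))
        assert np.allclose(
            t.compose(u).apply(pts), t.apply(u.apply(pts)), atol=1e-9
        )


def test_ransac_recovers_exact_plane():
    xy = np.mgrid[0:10, 0:10].reshape(2, -1).T.astype(float)
    cloud = PointCloud(np.column_stack([xy, np.ones(len(xy))]))
    plane = fit_plane_ransac(cloud, seed=1)
    assert np.allclose(plane.normal, [0, 0, 1], atol=1e-9)
    assert plane.offset == pytest.approx(1.0, abs=1e-9)
    assert plane.inlier_mask.all()


def test_ransac_excludes_gross_outliers(rng):
    xy = rng.uniform(0, 5, size=(200, 2))
    z = 0.3 * xy[:, 0] - 0.1 * xy[:, 1] + 2.0
    pts = np.column_stack([xy, z])
    n_out = 20
    outliers = pts[:n_out].copy()
    outliers[:, 2] += rng.uniform(0.5, 3.0, n_out) * rng.choice([-1, 1], n_out)
    cloud = PointCloud(np.vstack([outliers, pts[n_out:]]))
    plane = fit_plane_ransac(cloud, dist_threshold=0.01, seed=7)
    assert not plane.inlier_mask[:n_out].any()
    assert plane.inlier_mask[n_out:].all()


def test_ransac_residual_sd_recovers_noise(rng):
    sigma = 0.004
    xy = rng.uniform(0, 3, size=(10_000, 2))
    z = 1.5 + rng.normal(0, sigma, len(xy))
    plane = fit_plane_ransac(PointCloud(np.column_stack([xy, z])),
                             dist_threshold=5 * sigma, seed=3)
    res = plane.residuals(np.column_stack([xy, z]))
    assert np.std(res[plane.inlier_mask]) == pytest.approx(sigma, rel=0.10)


def test_ransac_rejects_collinear_points():
    line = np.column_stack([np.linspace(0, 1, 10), np.zeros(10), np.zeros(10)])
    with pytest.raises(DomainError):
        fit_plane_ransac(PointCloud(line), seed=0)


def test_face_distance_zero_on_side_face():
    z = 2.0
    x = z * math.tan(math.radians(70) / 2)
    cloud = PointCloud([[x, 0.0, z]])
    d = frustum_face_distances(cloud, FORWARD, SPEC)
    assert d[0] == pytest.approx(0.0, abs=1e-9)


def test_face_distance_boresight_closed_form():
    z = 2.5
    cloud = PointCloud([[0.0, 0.0, z]])
    d = frustum_face_distances(cloud, FORWARD, SPEC)
    expected = min(
        z * math.sin(math.radians(35)),  # horizontal side planes
        z * math.sin(math.radians(30)),  # vertical side planes
        z - SPEC.min_range,
        SPEC.max_range - z,
    )
    assert d[0] == pytest.approx(expected, abs=1e-9)


def test_face_distances_match_sampled_mesh_oracle(rng):
    mesh = frustum_boundary_mesh(FORWARD, SPEC)
    # dense point samples on every face as a brute-force oracle
    m = 140
    r1, r2 = np.meshgrid(np.linspace(0, 1, m), np.linspace(0, 1, m))
    r1, r2 = r1.ravel(), r2.ravel()
    keep = r1 + r2 <= 1.0
    samples = np.vstack(
        [
            tri[0]
            + r1[keep, None] * (tri[1] - tri[0])
            + r2[keep, None] * (tri[2] - tri[0])
            for tri in mesh
        ]
    )
    max_edge = max(
        np.linalg.norm(tri[i] - tri[j], axis=0).max()
        for tri in mesh
        for i, j in ((0, 1), (1, 2), (2, 0))
    )
    points = rng.uniform([-3, -3, 0], [3, 3, 5], size=(15, 3))
    got = frustum_face_distances(PointCloud(points), FORWARD, SPEC)
    oracle = np.array(
        [np.linalg.norm(samples - p, axis=1).min() for p in points]
    )
    assert np.all(got <= oracle + 1e-9)  # exact distance cannot exceed sampled
    assert np.all(oracle - got <= max_edge / (m - 1) + 1e-9)
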