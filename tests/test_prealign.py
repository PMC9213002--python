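import numpy as np
import pytest

from nucalign import (LandmarkCloud, affine_fit, apply_transform, cpd_refine,
                      tps_fit)
from nucalign.landmarks_io import CpdParams
from nucalign.prealign import DegenerateFitError, SpatialTransform


@pytest.fixture
def generic_points(rng):
    return rng.uniform(-20, 20, size=(8, 3))


class TestAffine:
    def test_identity_recovered_from_identical_points(self, generic_points):
        t = affine_fit(generic_points[:5], generic_points[:5])
        np.testing.assert_allclose(t.matrix, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.offset, 0, atol=1e-8)

    def test_known_affine_map_recovered_to_1e9(self, generic_points):
        A = np.array([[1.2, 0.1, -0.3], [0.0, 0.9, 0.2], [0.4, -0.1, 1.1]])
        b = np.array([3.0, -2.0, 7.0])
        dst = generic_points[:6] @ A.T + b
        t = affine_fit(generic_points[:6], dst)
        np.testing.assert_allclose(t.matrix, A, atol=1e-9)
        np.testing.assert_allclose(t.offset, b, atol=1e-9)

    def test_least_squares_beats_perturbed_candidates(self, generic_points, rng):
        src = generic_points
        dst = src @ np.diag([1.1, 0.95, 1.0]) + rng.normal(scale=0.5, size=src.shape)
        t = affine_fit(src, dst)
        base = ((t(src) - dst) ** 2).sum()
        for _ in range(20):
            m = t.matrix + rng.normal(scale=0.01, size=(3, 3))
            o = t.offset + rng.normal(scale=0.01, size=3)
            perturbed = ((src @ m.T + o - dst) ** 2).sum()
            assert base <= perturbed + 1e-12

    def test_coplanar_source_raises_rank_error(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 3, 0]], float)
        with pytest.raises(DegenerateFitError, match="dimension"):
            affine_fit(src, src)

    def test_not_worse_than_best_rigid_fit(self, generic_points, rng):
        from scipy.spatial.transform import Rotation
        src = generic_points
        R = Rotation.from_euler("xyz", [0.3, -0.2, 0.5]).as_matrix()
        dst = src @ R.T + rng.normal(scale=0.3, size=src.shape)
        t = affine_fit(src, dst)
        # Kabsch rigid fit on the same pairs
        sc, dc = src - src.mean(0), dst - dst.mean(0)
        U, _, Vt = np.linalg.svd(sc.T @ dc)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        Rr = Vt.T @ np.diag([1, 1, d]) @ U.T
        rigid = ((sc @ Rr.T - dc) ** 2).sum()
        assert ((t(src) - dst) ** 2).sum() <= rigid + 1e-9


class TestTps:
    def test_zero_lambda_interpolates_control_points(self, rng):
        src = rng.uniform(0, 50, size=(10, 3))
        dst = src + rng.normal(scale=2.0, size=src.shape)
        t = tps_fit(src, dst, 0.0)
        diam = np.linalg.norm(src.max(0) - src.min(0))
        assert np.abs(t(src) - dst).max() < 1e-6 * diam

    def test_affine_targets_give_vanishing_kernel_weights(self, rng):
        src = rng.uniform(0, 50, size=(9, 3))
        A = np.array([[1.1, 0.0, 0.2], [0.1, 0.9, 0.0], [0.0, 0.1, 1.05]])
        dst = src @ A.T + [1.0, 2.0, 3.0]
        t = tps_fit(src, dst, 0.0)
        assert np.abs(t.tps_weights).max() < 1e-8
        ta = affine_fit(src, dst)
        probe = rng.uniform(0, 50, size=(5, 3))
        np.testing.assert_allclose(t(probe), ta(probe), atol=1e-6)

    def test_residual_monotone_in_lambda_and_affine_limit(self, rng):
        src = rng.uniform(0, 50, size=(12, 3))
        dst = src + rng.normal(scale=3.0, size=src.shape)
        residuals = [tps_fit(src, dst, lam).residual for lam in (0.0, 1.0, 10.0, 100.0)]
        assert all(a <= b + 1e-9 for a, b in zip(residuals, residuals[1:]))
        big = tps_fit(src, dst, 1e7)
        ta = affine_fit(src, dst)
        probe = rng.uniform(0, 50, size=(6, 3))
        np.testing.assert_allclose(big(probe), ta(probe), atol=1e-2)

    def test_coincident_control_points_rejected(self):
        src = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        with pytest.raises(DegenerateFitError):
            tps_fit(src, src, 0.0)


class TestCpd:
    def test_self_registration_moves_almost_nothing(self, rng):
        pts = rng.uniform(0, 40, size=(60, 3))
        cloud = LandmarkCloud(points=pts)
        t = cpd_refine(cloud, cloud)
        diam = cloud.diameter
        assert np.linalg.norm(t.displacements, axis=1).mean() <= 0.01 * diam

    def test_recovers_smooth_sinusoidal_warp(self, rng):
        pts = rng.uniform(0, 40, size=(80, 3))
        cloud = LandmarkCloud(points=pts)
        diam = cloud.diameter
        warped = pts.copy()
        warped[:, 1] += 0.03 * diam * np.sin(2 * np.pi * pts[:, 0] / diam)
        target = LandmarkCloud(points=warped)
        from scipy.spatial import cKDTree
        before = cKDTree(warped).query(pts)[0].mean()
        t = cpd_refine(cloud, target)
        after = cKDTree(warped).query(pts + t.displacements)[0].mean()
        assert after < before

    def test_outliers_barely_move_the_inlier_field(self, rng):
        pts = rng.uniform(0, 40, size=(70, 3))
        cloud = LandmarkCloud(points=pts)
        diam = cloud.diameter
        clean = cpd_refine(cloud, LandmarkCloud(points=pts + 0.5))
        outliers = rng.uniform(-40, 80, size=(5, 3))
        noisy_target = LandmarkCloud(points=np.vstack([pts + 0.5, outliers]))
        noisy = cpd_refine(cloud, noisy_target, CpdParams(outlier_weight=0.1))
        drift = np.linalg.norm(noisy.displacements - clean.displacements, axis=1)
        assert drift.mean() <= 0.02 * diam


class TestApplyTransform:
    def test_identity_and_translation(self, generic_cloud):
        ident = SpatialTransform(kind="affine", matrix=np.eye(3), offset=np.zeros(3))
        np.testing.assert_allclose(apply_transform(ident, generic_cloud).points,
                                   generic_cloud.points)
        shift = SpatialTransform(kind="affine", matrix=np.eye(3),
                                 offset=np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(apply_transform(shift, generic_cloud).points,
                                   generic_cloud.points + [1, 2, 3])

    def test_affine_composition_matches_matrix_product(self, generic_cloud, rng):
        A = SpatialTransform(kind="affine", matrix=rng.normal(size=(3, 3)),
                             offset=rng.normal(size=3))
        B = SpatialTransform(kind="affine", matrix=rng.normal(size=(3, 3)),
                             offset=rng.normal(size=3))
        two_step = apply_transform(B, apply_transform(A, generic_cloud))
        composed = SpatialTransform(kind="affine", matrix=B.matrix @ A.matrix,
                                    offset=B.matrix @ A.offset + B.offset)
        np.testing.assert_allclose(two_step.points,
                                   apply_transform(composed, generic_cloud).points,
                                   atol=1e-9)

    def test_displacement_field_rejects_foreign_cloud(self, generic_cloud, rng):
        t = cpd_refine(generic_cloud, generic_cloud)
        other = LandmarkCloud(points=generic_cloud.points + 1.0)
        with pytest.raises(ValueError, match="not fitted"):
            apply_transform(t, other)

    def test_names_and_metadata_untouched(self, generic_cloud):
        shift = SpatialTransform(kind="affine", matrix=np.eye(3),
                                 offset=np.array([5.0, 0.0, 0.0]))
        out = apply_transform(shift, generic_cloud)
        assert out.names == generic_cloud.names
        assert out.source_id == generic_cloud.source_id
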