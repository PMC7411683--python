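"""4PCS primitives, rigid fitting, ICP and the registration error metric."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from girthkit import features as ft
from girthkit import preprocess as pp
from girthkit import register as rg
from girthkit import synthpig
from girthkit.types import (DegenerateGeometryError, PipelineConfig,
                            PointCloud, RegistrationError, RigidTransform)


def random_rigid(rng: np.random.Generator) -> RigidTransform:
    R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    return RigidTransform(R, rng.uniform(-1, 1, 3))


class TestMaxPairLength:
    def test_unit_cube_diagonal(self):
        corners = np.array(np.meshgrid([0, 1], [0, 1], [0, 1])).T.reshape(-1, 3)
        m = rg.max_pair_length(PointCloud(corners), 1.0)
        assert m == pytest.approx(np.sqrt(3))
        assert rg.max_pair_length(PointCloud(corners), 0.5) == pytest.approx(np.sqrt(3) / 2)

    def test_matches_bruteforce_bbox(self, rng):
        pts = rng.random((300, 3)) * [1.2, 0.4, 0.3]
        lo = np.array([pts[:, i].min() for i in range(3)])
        hi = np.array([pts[:, i].max() for i in range(3)])
        expected = 0.5 * np.linalg.norm(hi - lo)
        assert rg.max_pair_length(PointCloud(pts), 0.5) == pytest.approx(expected)


class TestScaleFactors:
    def test_symmetric_cross(self):
        r1, r2, e = rg.scale_factors([0, 0, 0], [2, 0, 0], [1, -1, 0], [1, 1, 0])
        assert (r1, r2) == (0.5, 0.5)
        np.testing.assert_allclose(e, [1, 0, 0])

    def test_hand_computed_quarter(self):
        r1, r2, e = rg.scale_factors([0, 0, 0], [4, 0, 0], [1, -1, 0], [1, 3, 0])
        assert r1 == pytest.approx(0.25)
        assert r2 == pytest.approx(0.25)
        np.testing.assert_allclose(e, [1, 0, 0])

    def test_parallel_segments_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            rg.scale_factors([0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0])

    def test_affine_invariance_under_rigid_motion(self, rng):
        quad = [np.array([0, 0, 0.0]), np.array([2, 0, 0.0]),
                np.array([0.7, -0.9, 0.0]), np.array([1.3, 1.1, 0.0])]
        r1_0, r2_0, _ = rg.scale_factors(*quad)
        for _ in range(50):
            T = random_rigid(rng)
            r1, r2, _ = rg.scale_factors(*(T.apply(p) for p in quad))
            assert abs(r1 - r1_0) <= 1e-9
            assert abs(r2 - r2_0) <= 1e-9


class TestBasisSearch:
    def test_planar_crossing_quad_found(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [1, -1, 0], [1, 1, 0.0]])
        bases = rg.find_coplanar_bases(PointCloud(pts), m=2.0, n_bases=1, seed=0)
        assert len(bases) == 1
        assert bases[0].r1 == pytest.approx(0.5, abs=1e-6)

    def test_collinear_cloud_fails(self):
        pts = np.column_stack([np.linspace(0, 1, 30), np.zeros(30), np.zeros(30)])
        with pytest.raises((RegistrationError, DegenerateGeometryError)):
            rg.find_coplanar_bases(PointCloud(pts), m=0.5, n_bases=2, seed=0)

    def test_deterministic_for_fixed_seed(self, rng):
        pts = rng.random((400, 3))
        b1 = rg.find_coplanar_bases(PointCloud(pts), m=0.8, n_bases=10, seed=3)
        b2 = rg.find_coplanar_bases(PointCloud(pts), m=0.8, n_bases=10, seed=3)
        assert len(b1) == len(b2)
        for x, y in zip(b1, b2):
            np.testing.assert_array_equal(x.points, y.points)


class TestCongruentSets:
    def _basis(self, pts):
        return rg.find_coplanar_bases(PointCloud(pts), m=0.8, n_bases=1, seed=1)[0]

    def test_rigid_copy_contains_transformed_basis(self, rng):
        pts = rng.random((120, 3))
        basis = self._basis(pts)
        T = random_rigid(rng)
        Q = PointCloud(T.apply(pts))
        # the e-coincidence tolerance must cover the basis's own
        # closest-approach gap (noisy segments never cross exactly)
        gap = np.linalg.norm((basis.a + basis.r1 * (basis.b - basis.a))
                             - (basis.c + basis.r2 * (basis.d - basis.c)))
        cands = rg.find_congruent_sets(Q, basis, congruence_tol=gap + 1e-6)

        def canon(arr):
            a = np.round(np.asarray(arr), 8)
            return tuple(map(tuple, a[np.lexsort(a.T[::-1])]))

        target = canon(T.apply(basis.points))
        assert any(canon(c) == target for c in cands)

    def test_scaled_cloud_has_no_candidates(self, rng):
        pts = rng.random((100, 3))
        basis = self._basis(pts)
        Q = PointCloud(pts * 2.0)
        assert rg.find_congruent_sets(Q, basis, congruence_tol=1e-3) == []

    def test_matches_exhaustive_enumeration(self, rng):
        pts = rng.random((60, 3))
        basis = self._basis(pts)
        tol = 0.02
        got = rg.find_congruent_sets(PointCloud(pts), basis, tol)
        # brute force: all ordered pairs for each segment, all coincidences
        d1 = np.linalg.norm(basis.b - basis.a)
        d2 = np.linalg.norm(basis.d - basis.c)
        expected = []
        n = len(pts)
        pairs1 = [(i, j) for i in range(n) for j in range(n) if i != j
                  and abs(np.linalg.norm(pts[i] - pts[j]) - d1) <= tol]
        pairs2 = [(i, j) for i in range(n) for j in range(n) if i != j
                  and abs(np.linalg.norm(pts[i] - pts[j]) - d2) <= tol]
        for (i, j) in pairs1:
            e1 = pts[i] + basis.r1 * (pts[j] - pts[i])
            for (k, l) in pairs2:
                e2 = pts[k] + basis.r2 * (pts[l] - pts[k])
                if np.linalg.norm(e1 - e2) <= tol and len({i, j, k, l}) == 4:
                    expected.append((i, j, k, l))
        got_keys = {tuple(np.round(c.ravel(), 9)) for c in got}
        exp_keys = {tuple(np.round(pts[list(q)].ravel(), 9)) for q in expected}
        assert got_keys == exp_keys


class TestRigidFit:
    def test_identity(self, rng):
        pts = rng.random((4, 3))
        T = rg.best_rigid_fit(pts, pts)
        np.testing.assert_allclose(T.matrix(), np.eye(4), atol=1e-12)

    def test_exact_quarter_turn(self, rng):
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        src = rng.random((4, 3))
        T = rg.best_rigid_fit(src, src @ R.T)
        np.testing.assert_allclose(T.rotation, R, atol=1e-9)

    def test_noisy_fit_matches_independent_kabsch(self, rng):
        src = rng.random((4, 3))
        T0 = random_rigid(rng)
        dst = T0.apply(src) + rng.normal(0, 0.001, (4, 3))
        T = rg.best_rigid_fit(src, dst)
        resid = np.linalg.norm(T.apply(src) - dst, axis=1)
        assert np.sqrt((resid ** 2).mean()) <= 0.003
        # independent oracle: centered cross-covariance SVD written out here
        cs, cd = src.mean(0), dst.mean(0)
        U, _, Vt = np.linalg.svd((src - cs).T @ (dst - cd))
        D = np.diag([1, 1, np.sign(np.linalg.det(Vt.T @ U.T))])
        R_oracle = Vt.T @ D @ U.T
        np.testing.assert_allclose(T.rotation, R_oracle, atol=1e-9)

    def test_collinear_source_rejected(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
        with pytest.raises(DegenerateGeometryError):
            rg.best_rigid_fit(src, src)


class TestCoarseAndICP:
    def test_exact_congruence_recovery(self, rng):
        pts = rng.random((300, 3)) * [1.0, 0.4, 0.2]
        T0 = random_rigid(rng)
        cfg = PipelineConfig(seed=3)
        res = rg.coarse_register(PointCloud(pts), PointCloud(T0.apply(pts)), cfg)
        err = np.linalg.norm(res.transform.apply(pts) - T0.apply(pts), axis=1)
        assert err.max() <= cfg.lcp_delta

    def test_unrelated_blobs_fail_or_score_low(self, rng):
        P = PointCloud(rng.random((150, 3)))
        Q = PointCloud(rng.random((150, 3)) + 5.0)
        try:
            res = rg.coarse_register(P, Q, PipelineConfig(seed=1))
            assert res.lcp_count < 0.5 * min(len(P), 400)
        except RegistrationError:
            pass

    def test_icp_fixed_point_from_exact_init(self, scan, cfg):
        res = rg.icp_refine(scan.side, scan.top, scan.true_transform, cfg)
        err = res.transform.compose(scan.true_transform.inverse())
        assert err.rotation_angle_deg() < 1.0
        assert np.linalg.norm(err.translation) < 0.015

    def test_registration_rmse_examples(self, rng):
        pts = rng.random((200, 3))
        T = random_rigid(rng)
        P = PointCloud(pts)
        Q_exact = PointCloud(T.apply(pts))
        assert rg.registration_rmse(P, Q_exact, T) == pytest.approx(0.0, abs=1e-9)
        Q_off = PointCloud(T.apply(pts) + [0.01, 0, 0])
        assert rg.registration_rmse(P, Q_off, T) == pytest.approx(1.0, rel=1e-6)

    def test_rmse_matches_bruteforce_nearest_neighbor(self, rng):
        pts = rng.random((150, 3))
        Q = pts + rng.normal(0, 0.005, pts.shape)
        got = rg.registration_rmse(PointCloud(pts), PointCloud(Q),
                                   RigidTransform.identity())
        D = np.linalg.norm(pts[:, None] - Q[None], axis=-1)
        assert got == pytest.approx(D.min(axis=1).mean() * 100.0, rel=1e-9)


class TestRegisterViews:
    def test_recovers_known_transform(self, pig, cfg):
        scan = synthpig.render_two_views(pig, noise_sigma=0.005, seed=77)
        side = pp.voxel_downsample(scan.side, cfg.voxel_size)
        top = pp.voxel_downsample(scan.top, cfg.voxel_size)
        side = ft.curvature_pca(side, cfg.curvature_k)
        regs = ft.build_regions(side, top, cfg)
        up = (synthpig.RIG_UP_IN_SIDE_FRAME, synthpig.RIG_UP_IN_TOP_FRAME, 10.0)
        res = rg.register_views(side, top, regs, cfg, up_prior=up)
        err = res.transform.compose(scan.true_transform.inverse())
        assert err.rotation_angle_deg() <= 2.0
        assert np.linalg.norm(err.translation) <= 0.02
        assert res.rmse_cm <= 2.5

    def test_deterministic(self, scan, cfg):
        side = ft.curvature_pca(pp.voxel_downsample(scan.side, cfg.voxel_size),
                                cfg.curvature_k)
        top = pp.voxel_downsample(scan.top, cfg.voxel_size)
        regs = ft.build_regions(side, top, cfg)
        up = (synthpig.RIG_UP_IN_SIDE_FRAME, synthpig.RIG_UP_IN_TOP_FRAME, 10.0)
        r1 = rg.register_views(side, top, regs, cfg, up_prior=up)
        r2 = rg.register_views(side, top, regs, cfg, up_prior=up)
        np.testing.assert_array_equal(r1.transform.matrix(), r2.transform.matrix())
        assert r1.rmse_cm == r2.rmse_cm
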