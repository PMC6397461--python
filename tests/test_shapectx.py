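"""Shape-context matching: binning, costs, assignment, TPS, distances."""

import itertools

import numpy as np
import pytest

from cellvfa import shapectx, syndata
from cellvfa.syndata import CellVideoParams


def circle(n=50, r=10.0, center=(30.0, 30.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)], 1)


class TestResample:
    def test_unit_square_four_points(self):
        # perimeter 4; canonical start is the vertex closest to angle 0 from
        # the centroid, i.e. (1, 1); samples then fall on the vertices
        sq = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        pts = shapectx.resample_contour(sq, 4)
        np.testing.assert_allclose(pts, [[1, 1], [0, 1], [0, 0], [1, 0]],
                                   atol=1e-12)

    def test_nested_resampling_consistency(self, rng):
        # samples at arc positions k L/n coincide with every other sample of
        # the 2n-point resampling (equal arc spacing by construction)
        c = circle(60) + rng.normal(0, 0.5, (60, 2))
        a = shapectx.resample_contour(c, 20)
        b = shapectx.resample_contour(c, 40)
        np.testing.assert_allclose(a, b[::2], atol=1e-9)

    def test_circle_points_on_radius(self):
        pts = shapectx.resample_contour(circle(200, r=10), 100)
        r = np.linalg.norm(pts - [30, 30], axis=1)
        # polygon chords lie slightly inside the true circle
        assert np.all(np.abs(r - 10) < 1e-2)
        assert r.std() < 1e-6

    def test_degenerate_contour_rejected(self):
        with pytest.raises(ValueError):
            shapectx.resample_contour(np.zeros((5, 2)), 10)


class TestShapeContext:
    def test_histogram_sums_when_all_within_outer_edge(self):
        H = shapectx.shape_context(circle(40))
        assert np.all(H.sum(axis=1) == 39)

    def test_scale_invariance_exact(self, rng):
        pts = rng.uniform(0, 10, (25, 2))
        np.testing.assert_array_equal(shapectx.shape_context(pts),
                                      shapectx.shape_context(pts * 7.3))

    def test_collinear_hand_binning(self):
        # reference (0,0): remaining points at angle 0, relative distances
        # 0.75 and 1.5 of the mean pairwise distance -> radial bins 3 and 4
        H = shapectx.shape_context(np.array([[0.0, 0], [1, 0], [2, 0]]))
        assert H[0].sum() == 2
        assert set(np.flatnonzero(H[0])) == {3 * 12, 4 * 12}


class TestChi2:
    def test_identity_and_hand_value(self):
        h = np.array([2.0, 0, 1])
        assert shapectx.chi2_cost(h, h) == 0.0
        assert shapectx.chi2_cost(np.array([2.0, 0]), np.array([0.0, 2])) == 2.0

    def test_symmetry(self, rng):
        for _ in range(20):
            a = rng.integers(0, 5, 60)
            b = rng.integers(0, 5, 60)
            assert shapectx.chi2_cost(a, b) == shapectx.chi2_cost(b, a)

    def test_matrix_matches_scalar(self, rng):
        H1 = rng.integers(0, 5, (6, 60))
        H2 = rng.integers(0, 5, (4, 60))
        C = shapectx.chi2_cost_matrix(H1, H2)
        for i in range(6):
            for j in range(4):
                assert C[i, j] == pytest.approx(
                    shapectx.chi2_cost(H1[i], H2[j]), abs=1e-12)

    def test_binning_mismatch_rejected(self):
        with pytest.raises(ValueError):
            shapectx.chi2_cost(np.zeros(60), np.zeros(59))


class TestHungarian:
    def test_hand_example(self):
        perm, total = shapectx.hungarian(np.array([[1.0, 2], [2, 1]]))
        np.testing.assert_array_equal(perm, [0, 1])
        assert total == 2.0

    def test_zero_diagonal(self):
        c = np.full((4, 4), 5.0)
        np.fill_diagonal(c, 0.0)
        perm, total = shapectx.hungarian(c)
        np.testing.assert_array_equal(perm, np.arange(4))
        assert total == 0.0

    def test_optimal_vs_exhaustive_5x5(self):
        for seed in range(50):
            c = np.random.default_rng(seed).uniform(0, 1, (5, 5))
            _, total = shapectx.hungarian(c)
            best = min(sum(c[i, p[i]] for i in range(5))
                       for p in itertools.permutations(range(5)))
            assert total == pytest.approx(best, abs=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            shapectx.hungarian(np.zeros((3, 4)))


class TestTps:
    def test_identity(self, rng):
        src = rng.uniform(0, 10, (12, 2))
        T = shapectx.fit_tps(src, src, 0.0)
        np.testing.assert_allclose(T.affine, [[0, 0], [1, 0], [0, 1]],
                                   atol=1e-8)
        np.testing.assert_allclose(T.weights, 0, atol=1e-8)

    def test_pure_translation_recovered(self, rng):
        src = rng.uniform(0, 10, (10, 2))
        T = shapectx.fit_tps(src, src + [5.0, -2.0], 0.0)
        probe = rng.uniform(-5, 15, (20, 2))
        np.testing.assert_allclose(T(probe), probe + [5.0, -2.0], atol=1e-7)

    def test_exact_interpolation_at_zero_regularization(self, rng):
        src = rng.uniform(0, 10, (15, 2))
        tgt = src + rng.normal(0, 1.0, (15, 2))
        T = shapectx.fit_tps(src, tgt, 0.0)
        np.testing.assert_allclose(T(src), tgt, atol=1e-8)

    def test_side_conditions(self, rng):
        src = rng.uniform(0, 10, (15, 2))
        tgt = src + rng.normal(0, 1.0, (15, 2))
        T = shapectx.fit_tps(src, tgt, 1e-3)
        P = np.hstack([np.ones((15, 1)), src])
        np.testing.assert_allclose(P.T @ T.weights, 0, atol=1e-8)

    def test_collinear_controls_singular(self):
        src = np.stack([np.arange(8.0), 2 * np.arange(8.0)], 1)
        with pytest.raises(np.linalg.LinAlgError):
            shapectx.fit_tps(src, src + 1.0, 0.0)


class TestShapeDistance:
    def test_zero_for_identical_sets(self):
        P = shapectx.resample_contour(circle(), 30)
        assert shapectx.shape_distance(P, P) == 0.0

    def test_nonnegative(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            P = r.uniform(0, 20, (10, 2))
            Q = r.uniform(0, 20, (10, 2))
            assert shapectx.shape_distance(P, Q) >= 0.0

    def test_matches_bruteforce_double_loop(self, rng):
        P = rng.uniform(0, 20, (10, 2))
        Q = rng.uniform(0, 20, (10, 2))
        HP = shapectx.shape_context(P)
        HQ = shapectx.shape_context(Q)
        fwd = np.mean([min(shapectx.chi2_cost(HP[i], HQ[j])
                           for j in range(10)) for i in range(10)])
        bwd = np.mean([min(shapectx.chi2_cost(HP[i], HQ[j])
                           for i in range(10)) for j in range(10)])
        assert shapectx.shape_distance(P, Q) == pytest.approx(fwd + bwd,
                                                              abs=1e-12)


class TestDeformationFeature:
    def test_identical_contours_all_zero(self):
        c = circle()
        for L in (1, 3):
            np.testing.assert_array_equal(
                shapectx.contour_deformation_feature(c, c, n=40, L=L),
                np.zeros(L))

    def test_pure_dilation_nearly_invisible(self):
        c = circle()
        D = shapectx.contour_deformation_feature(c, (c - 30) * 2 + 30,
                                                 n=40, L=3)
        assert np.all(D < 1e-3)

    def test_translation_and_scale_invariance(self):
        p = CellVideoParams(deform_amplitude=0.25, frame_count=6,
                            noise_sigma=0)
        cs = syndata.make_contour_sequence(p, seed=5)
        D0 = shapectx.contour_deformation_feature(cs[0], cs[4], n=60, L=4)
        D1 = shapectx.contour_deformation_feature(
            cs[0] + [13.7, -8.2], cs[4] + [13.7, -8.2], n=60, L=4)
        D2 = shapectx.contour_deformation_feature(cs[0] * 3.1, cs[4] * 3.1,
                                                  n=60, L=4)
        assert np.abs(D0 - D1).max() < 1e-6
        assert np.abs(D0 - D2).max() < 1e-6

    def test_length_and_nonnegativity(self):
        p = CellVideoParams(deform_amplitude=0.2, frame_count=5)
        cs = syndata.make_contour_sequence(p, seed=2)
        D = shapectx.contour_deformation_feature(cs[0], cs[4], n=50, L=7)
        assert D.shape == (7,)
        assert np.all(D >= 0)

    def test_rejects_bad_iteration_count(self):
        c = circle()
        with pytest.raises(ValueError):
            shapectx.contour_deformation_feature(c, c, n=40, L=0)
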