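"""Compact encodings: FV / VLAD-k / H-VLAD, codebooks, PCA and TPP."""

import numpy as np
import pytest

from cellvfa import aggregate
from cellvfa.aggregate import GmmCodebook, KmeansCodebook


def ssr(z):
    return np.sign(z) * np.sqrt(np.abs(z))


def literal_fisher_vector(X, gmm):
    """Per-term evaluation of the FV with explicit loops (test oracle)."""
    N, D = X.shape
    K = gmm.K
    sd = np.sqrt(gmm.variances)
    # posteriors
    q = np.zeros((K, N))
    for i in range(N):
        logp = np.zeros(K)
        for k in range(K):
            logp[k] = (np.log(gmm.weights[k])
                       - 0.5 * np.sum(np.log(2 * np.pi * gmm.variances[k]))
                       - 0.5 * np.sum((X[i] - gmm.means[k]) ** 2
                                      / gmm.variances[k]))
        m = logp.max()
        p = np.exp(logp - m)
        q[:, i] = p / p.sum()
    blocks = []
    for k in range(K):
        u = np.zeros(D)
        v = np.zeros(D)
        for i in range(N):
            z = (X[i] - gmm.means[k]) / sd[k]
            u += q[k, i] * z
            v += q[k, i] * (z**2 - 1.0)
        blocks.append(u / (N * np.sqrt(gmm.weights[k])))
        blocks.append(v / (N * np.sqrt(2.0 * gmm.weights[k])))
    out = ssr(np.concatenate(blocks))
    return out / np.linalg.norm(out)


class TestPca:
    def test_full_dimension_is_lossless_rotation(self, rng):
        X = rng.normal(size=(50, 6))
        p = aggregate.fit_pca(X, 6)
        Z = p.transform(X)
        back = Z @ p.components + p.mean
        np.testing.assert_allclose(back, X, atol=1e-9)

    def test_planar_data_exactly_recovered_in_2d(self, rng):
        basis = rng.normal(size=(2, 5))
        X = rng.normal(size=(40, 2)) @ basis + rng.normal(size=5)
        p = aggregate.fit_pca(X, 2)
        back = p.transform(X) @ p.components + p.mean
        assert np.abs(back - X).max() < 1e-9

    def test_insufficient_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            aggregate.fit_pca(rng.normal(size=(3, 5)), 4)


class TestGmm:
    def test_recovers_separated_means(self, rng):
        n = 400
        X = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(10, 1, (n, 2))])
        gmm = aggregate.fit_gmm(X, 2, seed=0)
        mu = gmm.means[np.argsort(gmm.means[:, 0])]
        assert np.abs(mu[0] - 0).max() < 3 / np.sqrt(n)
        assert np.abs(mu[1] - 10).max() < 3 / np.sqrt(n)

    def test_deterministic_and_normalized(self, rng):
        X = rng.normal(size=(80, 3))
        a = aggregate.fit_gmm(X, 4, seed=7)
        b = aggregate.fit_gmm(X, 4, seed=7)
        np.testing.assert_array_equal(a.means, b.means)
        assert a.weights.sum() == pytest.approx(1.0)
        assert np.all(a.weights > 0)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            aggregate.fit_gmm(rng.normal(size=(5, 2)), 6, seed=0)


class TestFisherVector:
    def test_k1_all_points_at_mean_closed_form(self):
        D = 4
        gmm = GmmCodebook(weights=np.array([1.0]),
                          means=np.zeros((1, D)),
                          variances=np.ones((1, D)))
        X = np.zeros((7, D))
        fv = aggregate.encode_fv(X, gmm)
        # u = 0; v = -1/sqrt(2) per dim pre-normalization; after SSR + l2
        # every v entry is -1/sqrt(D)
        np.testing.assert_allclose(fv[:D], 0, atol=1e-12)
        np.testing.assert_allclose(fv[D:], -1 / np.sqrt(D), atol=1e-12)

    def test_length_and_unit_norm(self, rng):
        X = rng.normal(size=(30, 5))
        gmm = aggregate.fit_gmm(X, 3, seed=1)
        fv = aggregate.encode_fv(rng.normal(size=(9, 5)), gmm)
        assert fv.shape == (2 * 5 * 3,)
        assert np.linalg.norm(fv) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_literal_formula(self, seed):
        r = np.random.default_rng(seed)
        K, D, N = r.integers(1, 4), r.integers(2, 5), r.integers(2, 8)
        gmm = GmmCodebook(weights=r.dirichlet(np.ones(K)),
                          means=r.normal(0, 2, (K, D)),
                          variances=r.uniform(0.5, 2.0, (K, D)))
        X = r.normal(0, 2, (N, D))
        np.testing.assert_allclose(aggregate.encode_fv(X, gmm),
                                   literal_fisher_vector(X, gmm), atol=1e-9)

    def test_empty_sequence_rejected(self):
        gmm = GmmCodebook(weights=np.ones(1), means=np.zeros((1, 2)),
                          variances=np.ones((1, 2)))
        with pytest.raises(ValueError):
            aggregate.encode_fv(np.empty((0, 2)), gmm)


def simple_kmeans_codebook(centers):
    centers = np.asarray(centers, dtype=float)
    return KmeansCodebook(centers=centers, mu=centers.copy(),
                          sigma=np.ones_like(centers),
                          gamma=np.zeros_like(centers))


class TestVlad:
    def test_descriptors_on_centers_give_flagged_zero_vector(self):
        cb = simple_kmeans_codebook([[0.0], [10.0]])
        out = aggregate.encode_vlad(np.array([[0.0], [10.0]]), cb, k_nn=1)
        assert np.linalg.norm(out) == 0.0

    def test_two_center_hand_example(self):
        # centers 0 and 10, X = {1, 9}, k_nn = 1 -> residual blocks (1, -1);
        # intra-l2 -> (1, -1); SSR -> (1, -1); global l2 -> (1, -1)/sqrt(2)
        cb = simple_kmeans_codebook([[0.0], [10.0]])
        out = aggregate.encode_vlad(np.array([[1.0], [9.0]]), cb, k_nn=1)
        np.testing.assert_allclose(out, [1 / np.sqrt(2), -1 / np.sqrt(2)],
                                   atol=1e-12)

    def test_knn1_matches_bruteforce_accumulation(self, rng):
        centers = rng.normal(0, 3, (5, 4))
        cb = simple_kmeans_codebook(centers)
        X = rng.normal(0, 3, (100, 4))
        blocks = np.zeros((5, 4))
        for x in X:
            k = int(np.argmin(((x - centers) ** 2).sum(1)))
            blocks[k] += x - centers[k]
        norms = np.linalg.norm(blocks, axis=1, keepdims=True)
        blocks = np.where(norms > 0, blocks / norms, 0.0)
        expected = ssr(blocks.ravel())
        expected = expected / np.linalg.norm(expected)
        np.testing.assert_allclose(aggregate.encode_vlad(X, cb, k_nn=1),
                                   expected, atol=1e-9)

    def test_knn_bounds_enforced(self, rng):
        cb = simple_kmeans_codebook(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            aggregate.encode_vlad(rng.normal(size=(4, 2)), cb, k_nn=4)

    def test_length(self, rng):
        cb = simple_kmeans_codebook(rng.normal(size=(6, 3)))
        out = aggregate.encode_vlad(rng.normal(size=(10, 3)), cb, k_nn=2)
        assert out.shape == (18,)


class TestHvlad:
    def test_matched_statistics_give_zero_blocks(self):
        # a symmetric two-point set reproduces the word's mean, spread and
        # (zero) skewness exactly
        cb = KmeansCodebook(centers=np.array([[0.0]]),
                            mu=np.array([[0.0]]),
                            sigma=np.array([[1.0]]),
                            gamma=np.array([[0.0]]))
        out = aggregate.encode_hvlad(np.array([[1.0], [-1.0]]), cb)
        assert np.linalg.norm(out) == 0.0

    def test_single_descriptor_block_pattern(self):
        cb = KmeansCodebook(centers=np.array([[0.0], [100.0]]),
                            mu=np.array([[0.5], [100.0]]),
                            sigma=np.array([[2.0], [1.0]]),
                            gamma=np.array([[0.3], [0.0]]))
        X = np.array([[3.0]])
        out = aggregate.encode_hvlad(X, cb)
        # word 0: u = 3 - 0.5 = 2.5, v = 0 - 4 = -4, s undefined -> 0;
        # word 1 empty -> zeros; then intra (|2.5|->1, |-4|->-1), SSR, l2
        pre = np.array([1.0, -1.0, 0.0, 0, 0, 0])
        expected = ssr(pre) / np.linalg.norm(ssr(pre))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_length(self, rng):
        X = rng.normal(size=(40, 3))
        cb = aggregate.fit_kmeans(X, 4, seed=0)
        out = aggregate.encode_hvlad(rng.normal(size=(10, 3)), cb)
        assert out.shape == (3 * 3 * 4,)

    def test_kmeans_codebook_statistics(self, rng):
        X = np.vstack([rng.normal(0, 1, (100, 2)),
                       rng.normal(8, 2, (100, 2))])
        cb = aggregate.fit_kmeans(X, 2, seed=0)
        order = np.argsort(cb.mu[:, 0])
        assert np.abs(cb.mu[order[0]]).max() < 0.5
        assert np.abs(cb.sigma[order[1]] - 2).max() < 0.5


class TestTpp:
    def test_window_arithmetic_n6(self):
        assert aggregate.tpp_windows(6) == [(0, 6), (0, 3), (3, 6),
                                            (0, 2), (2, 4), (4, 6)]

    def test_remainders_go_to_early_windows(self):
        assert aggregate.tpp_windows(7) == [(0, 7), (0, 4), (4, 7),
                                            (0, 3), (3, 5), (5, 7)]

    def test_too_short_sequence_rejected_with_minimum(self):
        with pytest.raises(ValueError, match="3"):
            aggregate.tpp_windows(2)

    def test_constant_sequence_gives_identical_blocks(self, rng):
        x = rng.normal(size=5)
        X = np.tile(x, (6, 1))
        out = aggregate.tpp(X, lambda Z: Z.mean(axis=0))
        blocks = out.reshape(6, -1)
        for b in blocks[1:]:
            np.testing.assert_allclose(b, blocks[0], atol=1e-12)

    def test_fv_tpp_dimension(self, rng):
        X = rng.normal(size=(60, 4))
        gmm = aggregate.fit_gmm(X, 2, seed=0)
        out = aggregate.encode_video(rng.normal(size=(9, 4)), gmm,
                                     scheme="fv", use_tpp=True)
        assert out.shape == (6 * 2 * 4 * 2,)
        assert np.linalg.norm(out) == pytest.approx(1.0)


class TestOrderSensitivity:
    def test_pooling_is_order_free_without_tpp(self, rng):
        X = rng.normal(size=(40, 3))
        gmm = aggregate.fit_gmm(X, 3, seed=0)
        km = aggregate.fit_kmeans(X, 3, seed=0)
        Z = rng.normal(size=(12, 3))
        perm = rng.permutation(12)
        for scheme, cb in (("fv", gmm), ("vlad", km), ("hvlad", km)):
            a = aggregate.encode_video(Z, cb, scheme=scheme, k_nn=2)
            b = aggregate.encode_video(Z[perm], cb, scheme=scheme, k_nn=2)
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_tpp_sees_temporal_order(self, rng):
        X = rng.normal(size=(40, 3))
        gmm = aggregate.fit_gmm(X, 3, seed=0)
        Z = np.vstack([rng.normal(0, 1, (6, 3)), rng.normal(5, 1, (6, 3))])
        a = aggregate.encode_video(Z, gmm, scheme="fv", use_tpp=True)
        b = aggregate.encode_video(Z[::-1], gmm, scheme="fv", use_tpp=True)
        assert np.abs(a - b).max() > 1e-6


class TestSerialization:
    def test_gmm_roundtrip(self, tmp_path, rng):
        X = rng.normal(size=(50, 3))
        gmm = aggregate.fit_gmm(X, 2, seed=0,
                                pca=aggregate.fit_pca(X, 2))
        path = tmp_path / "cb.json"
        aggregate.save_codebook(path, gmm, "fv", seed=0)
        back = aggregate.load_codebook(path)
        np.testing.assert_allclose(back.means, gmm.means)
        np.testing.assert_allclose(back.pca.components, gmm.pca.components)

    def test_kmeans_roundtrip(self, tmp_path, rng):
        X = rng.normal(size=(50, 3))
        km = aggregate.fit_kmeans(X, 3, seed=0)
        path = tmp_path / "cb.json"
        aggregate.save_codebook(path, km, "vlad", seed=0)
        back = aggregate.load_codebook(path)
        np.testing.assert_allclose(back.centers, km.centers)
        np.testing.assert_allclose(back.gamma, km.gamma)
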