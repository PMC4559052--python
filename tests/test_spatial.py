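"""Isolation by distance, connection networks, Moran's I and spatial PCA."""

import numpy as np
import pytest

import colonystruct as cs
from colonystruct.model import GroupFrequencies
from conftest import mantel_r_oracle, morans_i_oracle


def gf(group_id, freqs):
    return GroupFrequencies(group_id, [np.asarray(f, float) for f in freqs],
                            np.array([10] * len(freqs)))


class TestEdwardsDistance:
    def test_identical_profiles(self):
        a = gf("a", [[0.5, 0.5], [0.2, 0.8]])
        assert cs.edwards_distance(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_alleles(self):
        a = gf("a", [[1.0, 0.0], [1.0, 0.0, 0.0]])
        b = gf("b", [[0.0, 1.0], [0.0, 0.5, 0.5]])
        assert cs.edwards_distance(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_worked_value(self):
        a = gf("a", [[1.0, 0.0]])
        b = gf("b", [[0.5, 0.5]])
        assert cs.edwards_distance(a, b) == pytest.approx(
            np.sqrt(1 - np.sqrt(0.5)), abs=1e-9
        )

    def test_empty_locus_dropped(self):
        a = GroupFrequencies("a", [np.array([1.0, 0.0]), np.zeros(2)],
                             np.array([10, 0]), empty_loci=[1])
        b = gf("b", [[1.0, 0.0], [0.5, 0.5]])
        assert cs.edwards_distance(a, b) == pytest.approx(0.0, abs=1e-12)


class TestMantel:
    def test_identity_and_reversal(self):
        rng = np.random.default_rng(0)
        pts = rng.random((10, 2))
        d = cs.geographic_distance_matrix(pts)
        r, p = cs.mantel_test(d, d, n_perm=99, seed=1)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(1 / 100)
        r2, _ = cs.mantel_test(d, d.max() - d, n_perm=9, seed=1)
        assert r2 == pytest.approx(-1.0, abs=1e-12)

    def test_r_matches_oracle(self):
        rng = np.random.default_rng(2)
        a = cs.geographic_distance_matrix(rng.random((8, 2)))
        b = cs.geographic_distance_matrix(rng.random((8, 2)))
        r, _ = cs.mantel_test(a, b, n_perm=9, seed=3)
        assert r == pytest.approx(mantel_r_oracle(a, b), abs=1e-12)

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            cs.mantel_test(np.zeros((3, 3)), np.zeros((4, 4)))


class TestIbdDensity:
    def test_integrates_to_one(self):
        rng = np.random.default_rng(4)
        d1 = cs.geographic_distance_matrix(rng.random((12, 2)))
        d2 = cs.geographic_distance_matrix(rng.random((12, 2)))
        out = cs.ibd_density(d1, d2)
        dx = out["x"][1] - out["x"][0]
        dy = out["y"][1] - out["y"][0]
        assert out["density"].min() >= 0
        assert out["density"].sum() * dx * dy == pytest.approx(1.0, abs=0.02)

    def test_bimodal_patches(self):
        # two well-separated patches of pairwise points -> two local maxima
        n = 12
        d_geo = np.zeros((n, n))
        d_gen = np.zeros((n, n))
        rng = np.random.default_rng(5)
        for i in range(n):
            for j in range(i):
                near = (i < n // 2) == (j < n // 2)
                d_geo[i, j] = d_geo[j, i] = (1 if near else 10) + rng.normal(0, 0.05)
                d_gen[i, j] = d_gen[j, i] = (0.1 if near else 0.8) + rng.normal(0, 0.01)
        out = cs.ibd_density(d_gen, d_geo, gridsize=80)
        dens = out["density"]
        # count strict local maxima above a support threshold
        peaks = 0
        for i in range(1, dens.shape[0] - 1):
            for j in range(1, dens.shape[1] - 1):
                w = dens[i - 1 : i + 2, j - 1 : j + 2]
                if dens[i, j] == w.max() and dens[i, j] > dens.max() / 10:
                    peaks += 1
        assert peaks >= 2

    def test_zero_variance_axis(self):
        d = np.zeros((5, 5))
        with pytest.raises(ValueError, match="zero-variance"):
            cs.ibd_density(d, d)


class TestKnnGraph:
    def test_collinear_tie_break(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        net = cs.knn_graph(coords, ["a", "b", "c"], K=1)
        assert net.adjacency[1, 0] == 1  # middle picks the lower-index endpoint
        assert net.adjacency[1, 2] == 0

    def test_rows_sum_to_one(self):
        ds, _ = cs.sim_dataset(cs.SimConfig(seed=1))
        net = cs.knn_graph(ds.coords(), ds.colonies, K=10)
        np.testing.assert_allclose(net.W.sum(axis=1), 1.0)
        assert np.all(np.diag(net.adjacency) == 0)

    def test_complete_graph(self):
        rng = np.random.default_rng(6)
        coords = rng.random((7, 2))
        net = cs.knn_graph(coords, [str(i) for i in range(7)], K=6)
        assert net.adjacency.sum() == 7 * 6

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            cs.knn_graph(np.zeros((3, 2)), ["a", "b", "c"], K=3)


class TestMoransI:
    def test_permutation_null_mean(self):
        rng = np.random.default_rng(7)
        coords = rng.random((15, 2))
        net = cs.knn_graph(coords, [str(i) for i in range(15)], K=4)
        z = rng.normal(size=15)
        vals = [cs.morans_i(z[rng.permutation(15)], net.W) for _ in range(10_000)]
        assert np.mean(vals) == pytest.approx(-1 / 14, abs=0.01)

    def test_two_blobs_high_positive(self):
        coords = np.vstack([np.random.default_rng(8).normal(0, 0.1, (10, 2)),
                            np.random.default_rng(9).normal(5, 0.1, (10, 2))])
        net = cs.knn_graph(coords, [str(i) for i in range(20)], K=3)
        z = np.array([1.0] * 10 + [-1.0] * 10)
        assert cs.morans_i(z, net.W) > 0.9

    def test_checkerboard_negative(self):
        # rook adjacency on a 4x4 grid, alternating values
        coords = np.array([[i, j] for i in range(4) for j in range(4)], float)
        z = np.array([(-1.0) ** (i + j) for i in range(4) for j in range(4)])
        W = np.zeros((16, 16))
        for a in range(16):
            for b in range(16):
                if abs(coords[a] - coords[b]).sum() == 1:
                    W[a, b] = 1
        W = W / W.sum(axis=1, keepdims=True)
        assert cs.morans_i(z, W) < -0.9

    def test_matches_oracle(self):
        rng = np.random.default_rng(10)
        coords = rng.random((9, 2))
        net = cs.knn_graph(coords, [str(i) for i in range(9)], K=3)
        z = rng.normal(size=9)
        assert cs.morans_i(z, net.W) == pytest.approx(
            morans_i_oracle(z, net.W), abs=1e-12
        )

    def test_constant_vector_error(self):
        with pytest.raises(ValueError):
            cs.morans_i(np.ones(5), np.eye(5))


@pytest.fixture(scope="module")
def clustered_scene():
    ds, truth = cs.sim_dataset(
        cs.SimConfig(colonies_per_cluster=26, family_mix=(1, 0, 0), seed=17)
    )
    freqs = cs.colony_allele_frequencies(ds)
    X, labels = cs.frequency_matrix(freqs, ds.loci)
    net = cs.knn_graph(ds.coords(), ds.colonies, K=10)
    clusters = np.array([t.cluster for t in truth])
    return X, labels, net, clusters


class TestSpca:
    def test_eigen_identity(self, clustered_scene):
        X, labels, net, _ = clustered_scene
        res = cs.spca(X, net, labels)
        err = np.nanmax(np.abs(res.eigenvalues - res.axis_variance * res.axis_moran))
        assert err < 1e-10

    def test_cluster_separation(self, clustered_scene):
        X, labels, net, clusters = clustered_scene
        res = cs.spca(X, net, labels)
        assert res.eigenvalues[0] > 3 * abs(res.eigenvalues[1])
        signs = res.scores[:, 0] > 0
        concordance = max(np.mean(signs == clusters), np.mean(signs != clusters))
        assert concordance >= 0.9

    def test_loadings_sum_to_one(self, clustered_scene):
        X, labels, net, _ = clustered_scene
        res = cs.spca(X, net, labels)
        np.testing.assert_allclose(res.loadings.sum(axis=0), 1.0, atol=1e-9)
        top = cs.loading_report(res, axis=0, top_k=3)
        assert len(top) == 3
        assert top[0][1] >= top[1][1] >= top[2][1]
        full = cs.loading_report(res, axis=0, top_k=10_000)
        assert len(full) == X.shape[1]

    def test_spatially_random_small_lambda(self):
        rng = np.random.default_rng(18)
        X = rng.random((30, 8))
        net = cs.knn_graph(rng.random((30, 2)), [str(i) for i in range(30)], K=5)
        res = cs.spca(X, net)
        total_var = (X - X.mean(0)).var(0).sum()
        assert abs(res.eigenvalues[0]) < 0.5 * total_var

    def test_complete_graph_matches_pca_ordering(self):
        # uniform complete-graph weights give z'Wz = -sum(z^2)/(n-1) for
        # centered z, so the criterion is -variance/(n-1): the plain-PCA
        # dominant axis is the largest-|eigenvalue| (most negative) sPCA axis
        rng = np.random.default_rng(19)
        X = rng.random((25, 6))
        coords = rng.random((25, 2))
        net = cs.knn_graph(coords, [str(i) for i in range(25)], K=24)
        res = cs.spca(X, net)
        order = np.argsort(-np.abs(res.eigenvalues))
        Xc = X - X.mean(0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        for axis in range(2):
            pc = Xc @ vt[axis]
            sp = res.scores[:, order[axis]]
            r = abs(np.corrcoef(pc, sp)[0, 1])
            assert r >= 0.99

    def test_planted_allele_tops_loadings(self):
        # one column with a strong spatial split dominates axis 1
        rng = np.random.default_rng(20)
        n = 40
        coords = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(8, 1, (20, 2))])
        X = rng.normal(0, 0.05, size=(n, 6))
        X[:20, 2] += 1.0
        net = cs.knn_graph(coords, [str(i) for i in range(n)], K=5)
        res = cs.spca(X, net, [f"a{i}" for i in range(6)])
        assert cs.loading_report(res, axis=0, top_k=1)[0][0] == "a2"

    def test_minimum_size(self):
        net = cs.knn_graph(np.array([[0.0, 0], [1, 0], [2, 0]]), list("abc"), K=1)
        with pytest.raises(ValueError):
            cs.spca(np.zeros((2, 3)), net)


class TestSpcaTests:
    def test_power_pattern(self, clustered_scene):
        X, _, net, _ = clustered_scene
        out = cs.spca_tests(X, net, n_perm=499, seed=21)
        assert out["global_p"] <= 0.01
        assert out["local_p"] > 0.05

    def test_permuted_data_not_significant(self, clustered_scene):
        X, _, net, _ = clustered_scene
        rng = np.random.default_rng(22)
        Xp = X[rng.permutation(X.shape[0])]
        out = cs.spca_tests(Xp, net, n_perm=199, seed=23)
        assert out["global_p"] > 0.01
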