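import numpy as np
import pytest

from connkit import ConnectivityMatrix
from connkit.metrics import (
    characteristic_path_length,
    compute_global_metrics,
    global_efficiency,
    local_efficiency,
    nodal_efficiency,
    sweep_and_integrate,
    to_distance,
    weighted_clustering,
)
from connkit.networks import apply_sparsity_threshold

from conftest import random_weighted_net


# ---------------------------------------------------------------------------
# Independent brute-force oracles (Floyd-Warshall; exhaustive triple loops)


def fw_distances(w):
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_onnela(w):
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return 0.0
    c = np.zeros(n)
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i:
                    continue
                total += ((w[i, j] / wmax) * (w[i, h] / wmax) * (w[j, h] / wmax)) ** (1 / 3)
        c[i] = total / (k * (k - 1))
    return c.mean()


def brute_barrat(w):
    n = w.shape[0]
    a = (w > 0).astype(float)
    c = np.zeros(n)
    for i in range(n):
        k = int(a[i].sum())
        s = w[i].sum()
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i:
                    continue
                total += (w[i, j] + w[i, h]) / 2 * a[i, j] * a[i, h] * a[j, h]
        c[i] = total / (s * (k - 1))
    return c.mean()


def brute_global_eff(d):
    n = d.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_local_eff(w):
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        nb = np.flatnonzero(w[i] > 0)
        if nb.size < 2:
            continue
        total += brute_global_eff(fw_distances(w[np.ix_(nb, nb)]))
    return total / n


def net_from(w, modality="structural"):
    w = np.asarray(w, dtype=float)
    return ConnectivityMatrix("t", modality, w,
                              tuple(f"R{i}" for i in range(w.shape[0])))


def sym_random(rng, n, density=0.7):
    w = rng.random((n, n))
    w[rng.random((n, n)) > density] = 0.0
    w = np.triu(w, 1)
    return w + w.T


# ---------------------------------------------------------------------------


class TestDistances:
    def test_single_edge_inverse_weight(self):
        d = to_distance(net_from([[0, 0.5], [0.5, 0]]))
        assert d[0, 1] == pytest.approx(2.0)

    def test_two_unit_hops(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        d = to_distance(net_from(w))
        assert d[0, 2] == pytest.approx(2.0)

    def test_matches_floyd_warshall(self, rng):
        for _ in range(20):
            w = sym_random(rng, 10)
            np.testing.assert_allclose(to_distance(net_from(w)), fw_distances(w), atol=1e-12)

    def test_disconnected_pair_is_inf(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        d = to_distance(net_from(w))
        assert np.isinf(d[0, 2])


class TestGlobalEfficiency:
    def test_complete_unit_network(self):
        w = 1.0 - np.eye(4)
        assert global_efficiency(to_distance(net_from(w))) == pytest.approx(1.0)

    def test_three_node_unit_path(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        assert global_efficiency(to_distance(net_from(w))) == pytest.approx(5 / 6)

    def test_edgeless_network(self):
        assert global_efficiency(to_distance(net_from(np.zeros((4, 4))))) == 0.0

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            global_efficiency(np.zeros((1, 1)))


class TestNodalEfficiency:
    def star(self, n_leaves):
        w = np.zeros((n_leaves + 1, n_leaves + 1))
        w[0, 1:] = w[1:, 0] = 1.0
        return w

    def test_hub_of_star(self):
        d = to_distance(net_from(self.star(4)))
        assert nodal_efficiency(d, 0) == pytest.approx(1.0)

    def test_leaf_of_three_leaf_star(self):
        d = to_distance(net_from(self.star(3)))
        assert nodal_efficiency(d, 1) == pytest.approx(2 / 3)

    def test_isolated_node(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        d = to_distance(net_from(w))
        assert nodal_efficiency(d, 2) == 0.0

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            nodal_efficiency(np.zeros((3, 3)), 5)

    def test_vector_mean_relates_to_global(self, rng):
        w = sym_random(rng, 8)
        d = to_distance(net_from(w))
        vec = nodal_efficiency(d)
        assert vec.mean() == pytest.approx(global_efficiency(d), abs=1e-12)


class TestPathLength:
    def test_complete_unit_network(self):
        w = 1.0 - np.eye(5)
        assert characteristic_path_length(to_distance(net_from(w))).value == pytest.approx(1.0)

    def test_three_node_unit_path(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        res = characteristic_path_length(to_distance(net_from(w)))
        assert res.value == pytest.approx(4 / 3)
        assert res.n_excluded_pairs == 0

    def test_disconnected_pairs_excluded_and_counted(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 0.5
        res = characteristic_path_length(to_distance(net_from(w)))
        assert res.value == pytest.approx((1.0 + 2.0) / 2)
        assert res.n_excluded_pairs == 4

    def test_fully_disconnected_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            characteristic_path_length(to_distance(net_from(np.zeros((3, 3)))))


class TestClustering:
    def test_unit_triangle(self):
        w = 1.0 - np.eye(3)
        assert weighted_clustering(net_from(w)) == pytest.approx(1.0)

    def test_path_has_no_triangles(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        assert weighted_clustering(net_from(w)) == 0.0

    def test_weak_edge_triangle_matches_brute_force(self):
        w = np.array([[0, 1, 1], [1, 0, 0.125], [1, 0.125, 0]])
        assert weighted_clustering(net_from(w)) == pytest.approx(brute_onnela(w), abs=1e-12)

    def test_negative_weight_rejected(self):
        w = np.array([[0, -1.0], [-1.0, 0]])
        with pytest.raises(ValueError):
            weighted_clustering(w)

    def test_barrat_variant_matches_brute_force(self, rng):
        for _ in range(20):
            w = sym_random(rng, 8)
            assert weighted_clustering(net_from(w), variant="barrat") == pytest.approx(
                brute_barrat(w), abs=1e-10)


class TestLocalEfficiency:
    def test_complete_unit_network(self):
        w = 1.0 - np.eye(4)
        assert local_efficiency(net_from(w)) == pytest.approx(1.0)

    def test_star_is_zero(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        assert local_efficiency(net_from(w)) == 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(15):
            w = sym_random(rng, 8)
            assert local_efficiency(net_from(w)) == pytest.approx(
                brute_local_eff(w), abs=1e-10)


class TestOracleSuite:
    def test_all_metrics_match_brute_force_on_random_graphs(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 13))
            w = sym_random(rng, n, density=float(rng.uniform(0.3, 1.0)))
            d_ref = fw_distances(w)
            d = to_distance(net_from(w))
            np.testing.assert_allclose(d, d_ref, atol=1e-10)
            assert global_efficiency(d) == pytest.approx(brute_global_eff(d_ref), abs=1e-10)
            nodal_ref = [
                sum(1 / d_ref[i, j] for j in range(n)
                    if j != i and np.isfinite(d_ref[i, j]) and d_ref[i, j] > 0) / (n - 1)
                for i in range(n)
            ]
            np.testing.assert_allclose(nodal_efficiency(d), nodal_ref, atol=1e-10)
            assert weighted_clustering(w) == pytest.approx(brute_onnela(w), abs=1e-10)
            assert local_efficiency(w) == pytest.approx(brute_local_eff(w), abs=1e-10)


class TestScaleAndSymmetryProperties:
    def test_weight_scaling(self, rng):
        w = sym_random(rng, 9)
        lam = 3.7
        d1, d2 = to_distance(net_from(w)), to_distance(net_from(w * lam))
        np.testing.assert_allclose(d2, d1 / lam, atol=1e-10)
        assert global_efficiency(d2) == pytest.approx(lam * global_efficiency(d1), abs=1e-10)
        np.testing.assert_allclose(
            np.asarray(nodal_efficiency(d2)), lam * np.asarray(nodal_efficiency(d1)), atol=1e-10)
        assert weighted_clustering(w * lam) == pytest.approx(weighted_clustering(w), abs=1e-12)

    def test_permutation_equivariance(self, rng):
        w = sym_random(rng, 10)
        perm = rng.permutation(10)
        wp = w[np.ix_(perm, perm)]
        m1 = compute_global_metrics(net_from(w))
        m2 = compute_global_metrics(net_from(wp))
        for name in ("c_w", "l_w", "e_loc", "e_glob"):
            assert getattr(m1, name) == pytest.approx(getattr(m2, name), abs=1e-10)
        np.testing.assert_allclose(m2.nodal, m1.nodal[perm], atol=1e-10)


class TestSweep:
    def test_constant_metric_integrates_to_rectangle(self, rng):
        # complete unit-weight network: thresholding keeps ties deterministically,
        # all kept weights are 1, so check the trapezoid rule on a constant directly
        levels = np.round(np.arange(0.1, 0.401, 0.01), 12)
        const = np.ones_like(levels)
        assert np.trapezoid(const, levels) == pytest.approx(0.3)

    def test_default_grid_has_31_levels(self, rng):
        net = random_weighted_net(rng, 12, density=1.0)
        sw = sweep_and_integrate(net)
        assert sw.sparsities.size == 31
        assert sw.sparsities[0] == pytest.approx(0.1)
        assert sw.sparsities[-1] == pytest.approx(0.4)

    def test_eglob_monotone_in_sparsity(self, rng):
        net = random_weighted_net(rng, 14, density=1.0)
        sw = sweep_and_integrate(net)
        eglob = sw.levels["E_glob"]
        assert np.all(np.diff(eglob) >= -1e-12)

    def test_integral_matches_independent_trapezoid(self, rng):
        net = random_weighted_net(rng, 12, density=1.0)
        sw = sweep_and_integrate(net)
        for name, vals in sw.levels.items():
            ref = sum(
                (vals[i] + vals[i + 1]) / 2 * (sw.sparsities[i + 1] - sw.sparsities[i])
                for i in range(len(vals) - 1)
            )
            assert sw.integrated[name] == pytest.approx(ref, abs=1e-12)

    def test_level_values_match_direct_computation(self, rng):
        net = random_weighted_net(rng, 10, density=1.0)
        sw = sweep_and_integrate(net, 0.2, 0.4, 0.1)
        for idx, s in enumerate(sw.sparsities):
            m = compute_global_metrics(apply_sparsity_threshold(net, float(s)))
            assert sw.levels["E_glob"][idx] == pytest.approx(m.e_glob, abs=1e-12)

    def test_too_few_levels_rejected(self, rng):
        net = random_weighted_net(rng, 8)
        with pytest.raises(ValueError):
            sweep_and_integrate(net, 0.1, 0.15, 0.2)
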