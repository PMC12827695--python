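import numpy as np
import pytest

from edgedyn.metrics import (
    auc_over_grid,
    characteristic_path_length,
    clustering_coefficient,
    degree_preserving_rewire,
    global_efficiency,
    global_metrics,
    local_efficiency,
    nodal_metrics,
    null_normalize,
)


# ---------------------------------------------------------------------------
# independent oracles: Floyd-Warshall distances + matrix-power path counting


def fw_distances(adj):
    n = len(adj)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0)
    d[np.asarray(adj, dtype=bool)] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    return d


def shortest_path_counts(adj, d):
    """sigma[s, t] = number of shortest s-t paths, via integer walk counts."""
    n = len(adj)
    a = np.asarray(adj, dtype=object)  # exact integer arithmetic
    powers = {1: a}
    maxd = int(max((x for x in d.ravel() if np.isfinite(x)), default=0))
    for k in range(2, maxd + 1):
        powers[k] = powers[k - 1] @ a
    sigma = np.zeros((n, n), dtype=object)
    for s in range(n):
        for t in range(n):
            if s == t or not np.isfinite(d[s, t]):
                continue
            sigma[s, t] = powers[int(d[s, t])][s, t]
    return sigma


def brute_betweenness(adj):
    """Pair-summed fractional-credit betweenness from the sigma decomposition."""
    n = len(adj)
    d = fw_distances(adj)
    sigma = shortest_path_counts(adj, d)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]):
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if d[s, v] + d[v, t] == d[s, t]:
                    bc[v] += (sigma[s, v] * sigma[v, t]) / sigma[s, t]
    return bc


def brute_global(adj):
    n = len(adj)
    d = fw_distances(adj)
    lp_vals, eg_vals = [], []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.isfinite(d[i, j]):
                lp_vals.append(d[i, j])
                eg_vals.append(1 / d[i, j])
            else:
                eg_vals.append(0.0)
    cp_vals = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        k = len(nb)
        if k < 2:
            cp_vals.append(0.0)
            continue
        links = sum(adj[u][v] for ui, u in enumerate(nb) for v in nb[ui + 1 :])
        cp_vals.append(2 * links / (k * (k - 1)))
    eloc_vals = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        if len(nb) < 2:
            eloc_vals.append(0.0)
            continue
        sub = [[adj[u][v] for v in nb] for u in nb]
        eloc_vals.append(brute_global(sub)["Eglob"])
    return {
        "Cp": float(np.mean(cp_vals)),
        "Lp": float(np.mean(lp_vals)) if lp_vals else 0.0,
        "Eglob": float(np.mean(eg_vals)) if eg_vals else 0.0,
        "Eloc": float(np.mean(eloc_vals)),
    }


def random_adj(n, p, rng):
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T


K4 = np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)
P4 = np.array([[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]])
STAR4 = np.array([[0, 1, 1, 1], [1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0]])


class TestGlobalMetrics:
    def test_complete_graph(self):
        gm = global_metrics(K4)
        assert gm == {"Cp": 1.0, "Lp": 1.0, "Eglob": 1.0, "Eloc": 1.0}

    def test_path_graph(self):
        gm = global_metrics(P4)
        assert gm["Lp"] == pytest.approx(10 / 6)
        assert gm["Eglob"] == pytest.approx((1 + 0.5 + 1 / 3 + 1 + 0.5 + 1) / 6)

    def test_star_no_triangles(self):
        assert clustering_coefficient(STAR4) == 0.0

    def test_empty_graph_warns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            gm = global_metrics(np.zeros((4, 4), dtype=int))
        assert all(v == 0.0 for v in gm.values())

    def test_kn_calibration_lp_equals_inverse_eglob(self):
        for n in (3, 5, 8):
            kn = np.ones((n, n), dtype=int) - np.eye(n, dtype=int)
            gm = global_metrics(kn)
            assert gm["Lp"] == 1.0 and gm["Eglob"] == 1.0

    def test_random_graphs_match_brute_force(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 9))
            adj = random_adj(n, rng.uniform(0.2, 0.8), rng)
            gm = global_metrics(adj)
            brute = brute_global(adj.tolist())
            for key in ("Cp", "Lp", "Eglob", "Eloc"):
                assert gm[key] == pytest.approx(brute[key], abs=1e-10), key

    def test_eglob_monotone_under_edge_subsets(self, rng):
        from edgedyn.frames import threshold_proportional

        fc = rng.normal(size=(10, 10))
        fc = (fc + fc.T) / 2
        np.fill_diagonal(fc, 0)
        graphs = threshold_proportional(fc, [0.1, 0.2, 0.3, 0.4])
        eg = [global_efficiency(graphs[s]) for s in (0.1, 0.2, 0.3, 0.4)]
        assert all(a <= b + 1e-12 for a, b in zip(eg, eg[1:]))


class TestNodalMetrics:
    def test_path_betweenness(self):
        nm = nodal_metrics(P4)
        np.testing.assert_allclose(nm["Bc"], [0, 2, 2, 0])

    def test_star_hub(self):
        nm = nodal_metrics(STAR4)
        assert nm["Bc"][0] == 3.0 and nm["Dc"][0] == 3.0

    def test_isolated_node(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        nm = nodal_metrics(adj)
        assert nm["Ne"][2] == 0 and nm["Dc"][2] == 0 and nm["Bc"][2] == 0

    def test_random_graphs_match_brute_force(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 9))
            adj = random_adj(n, rng.uniform(0.2, 0.8), rng)
            nm = nodal_metrics(adj)
            np.testing.assert_allclose(nm["Bc"], brute_betweenness(adj), atol=1e-9)
            d = fw_distances(adj)
            with np.errstate(divide="ignore"):
                inv = np.where(np.isfinite(d) & (d > 0), 1 / d, 0.0)
            np.testing.assert_allclose(nm["Ne"], inv.sum(axis=1) / (n - 1), atol=1e-12)
            np.testing.assert_allclose(nm["Dc"], adj.sum(axis=1))


class TestRewiring:
    def test_degree_sequence_preserved(self, rng):
        for _ in range(20):
            adj = random_adj(12, 0.3, rng)
            null = degree_preserving_rewire(adj, n_swaps=50, rng=rng)
            np.testing.assert_array_equal(null.sum(axis=1), adj.sum(axis=1))
            assert np.array_equal(null, null.T) and not np.any(np.diag(null))

    def test_deterministic_with_seed(self):
        adj = random_adj(10, 0.4, np.random.default_rng(3))
        a = degree_preserving_rewire(adj, 30, np.random.default_rng(7))
        b = degree_preserving_rewire(adj, 30, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_infeasible_graph_returns_original(self, caplog):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        with caplog.at_level("WARNING"):
            null = degree_preserving_rewire(adj, 10, np.random.default_rng(0))
        np.testing.assert_array_equal(null, adj)


class TestNullNormalize:
    def test_identity_ensemble_gives_unity(self):
        adj = random_adj(10, 0.4, np.random.default_rng(0))
        sw, ens = null_normalize(adj, n_nulls=1, rewires_per_edge=0)
        assert sw["gamma"] == 1.0 and sw["lambda"] == 1.0 and sw["sigma"] == 1.0

    def test_sigma_is_ratio_bit_exact(self, rng):
        adj = random_adj(14, 0.3, rng)
        sw, _ = null_normalize(adj, n_nulls=5, rewires_per_edge=3, seed=1)
        assert sw["sigma"] == sw["gamma"] / sw["lambda"]

    def test_ring_lattice_high_gamma(self):
        # ring lattice N=50, each node tied to 2 neighbors per side
        n = 50
        adj = np.zeros((n, n), dtype=int)
        for i in range(n):
            for step in (1, 2):
                j = (i + step) % n
                adj[i, j] = adj[j, i] = 1
        sw, _ = null_normalize(adj, n_nulls=20, rewires_per_edge=10, seed=42)
        assert sw["gamma"] > 1.5

    def test_too_few_edges(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 0] = 1
        with pytest.raises(ValueError):
            null_normalize(adj, n_nulls=2, rewires_per_edge=2)


class TestAuc:
    def test_constant(self):
        grid = [0.05, 0.15, 0.25]
        assert auc_over_grid([2.0, 2.0, 2.0], grid) == pytest.approx(2.0 * 0.2)

    def test_linear(self):
        assert auc_over_grid([0.0, 1.0], [0.0, 1.0]) == pytest.approx(0.5)

    def test_matches_brute_force(self, rng):
        grid = np.sort(rng.random(12))
        vals = rng.normal(size=12)
        manual = sum(
            (grid[i + 1] - grid[i]) * (vals[i] + vals[i + 1]) / 2 for i in range(11)
        )
        assert auc_over_grid(vals, grid) == pytest.approx(manual, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            auc_over_grid([1.0, 2.0], [0.1, 0.2, 0.3])
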