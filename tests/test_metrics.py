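import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import motorscn.metrics as gm
import _oracles as oracle


def complete(n):
    return ~np.eye(n, dtype=bool)


def path_graph(n):
    a = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = True
    return a


def star(n):
    a = np.zeros((n, n), dtype=bool)
    a[0, 1:] = a[1:, 0] = True
    return a


def ring(n):
    a = path_graph(n)
    a[0, n - 1] = a[n - 1, 0] = True
    return a


class TestClosedForms:
    def test_complete_graph_k20(self):
        g = gm.global_metrics(complete(20))
        assert g.global_efficiency == pytest.approx(1.0)
        assert g.mean_clustering == pytest.approx(1.0)
        assert g.char_path_length == pytest.approx(1.0)

    def test_path_graph_three_nodes_efficiency(self):
        # pairs (0,1),(1,2) at distance 1; (0,2) at distance 2
        assert gm.global_efficiency(path_graph(3)) == pytest.approx((1 + 1 + 0.5) / 3)

    @pytest.mark.parametrize("n", [4, 5, 8])
    def test_star_graph_assortativity_minus_one(self, n):
        assert gm.degree_assortativity(star(n)) == pytest.approx(-1.0)

    def test_star_center_betweenness_counts_routed_pairs(self):
        # star on 5 nodes: 6 leaf pairs all routed through the centre
        cb, _ = gm.betweenness(star(5))
        assert cb[0] == pytest.approx(6.0)
        assert np.allclose(cb[1:], 0.0)

    def test_clustering_one_in_complete_graph(self):
        assert np.allclose(gm.clustering_coefficients(complete(20)), 1.0)

    def test_participation_zero_within_single_module(self):
        part = np.array(["a"] * 5)
        assert np.allclose(gm.participation_coefficients(complete(5), part), 0.0)

    def test_participation_even_split(self):
        # node 0 with one edge into each of two modules: 1 - 2*(1/2)^2 = 0.5
        a = np.zeros((3, 3), dtype=bool)
        a[0, 1] = a[1, 0] = a[0, 2] = a[2, 0] = True
        part = np.array(["x", "x", "y"])
        assert gm.participation_coefficients(a, part)[0] == pytest.approx(0.5)

    def test_empty_graph_flags(self):
        a = np.zeros((5, 5), dtype=bool)
        g = gm.global_metrics(a)
        assert g.global_efficiency == 0.0
        assert np.isnan(g.char_path_length)


class TestOracleEquivalence:
    """Every metric equals brute-force enumeration on random small graphs,
    and agrees with networkx as an independent library cross-check."""

    @pytest.mark.parametrize("case", range(40))
    def test_matches_brute_force_and_networkx(self, case):
        rng = np.random.default_rng(case)
        n = int(rng.integers(3, 8))
        adj = oracle.random_graph(n, rng.uniform(0.2, 0.8), rng)
        A = adj.tolist()
        G = nx.from_numpy_array(adj.astype(int))

        assert gm.global_efficiency(adj) == pytest.approx(oracle.global_efficiency(A))
        assert gm.global_efficiency(adj) == pytest.approx(nx.global_efficiency(G))

        cpl = gm.char_path_length(adj)
        assert cpl == pytest.approx(oracle.char_path_length(A), nan_ok=True)

        assert np.allclose(gm.clustering_coefficients(adj), oracle.clustering(A))
        nx_c = np.array([nx.clustering(G)[i] for i in range(n)])
        assert np.allclose(gm.clustering_coefficients(adj), nx_c)

        assert np.allclose(gm.local_efficiencies(adj), oracle.local_efficiency(A))
        assert gm.local_efficiencies(adj).mean() == pytest.approx(
            nx.local_efficiency(G))

        ours = gm.degree_assortativity(adj)
        theirs = oracle.assortativity(A)
        if np.isnan(theirs):
            assert np.isnan(ours)
        else:
            assert ours == pytest.approx(theirs)

        cb, ceb = gm.betweenness(adj)
        ocb, oceb = oracle.betweenness_by_path_enumeration(A)
        assert np.allclose(cb, ocb)
        for e, v in oceb.items():
            assert ceb.get(e, 0.0) == pytest.approx(v)
        nx_cb = nx.betweenness_centrality(G, normalized=False)
        assert np.allclose(cb, [nx_cb[i] for i in range(n)])
        nx_eb = nx.edge_betweenness_centrality(G, normalized=False)
        for e, v in nx_eb.items():
            assert ceb.get(tuple(sorted(e)), 0.0) == pytest.approx(v)

        part = np.array([str(int(x)) for x in rng.integers(0, 3, n)])
        assert np.allclose(gm.participation_coefficients(adj, part),
                           oracle.participation(A, part.tolist()))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_relabeling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        adj = oracle.random_graph(n, 0.4, rng)
        perm = rng.permutation(n)
        padj = adj[np.ix_(perm, perm)]
        g1, g2 = gm.global_metrics(adj), gm.global_metrics(padj)
        for f in ("global_efficiency", "mean_clustering", "char_path_length",
                  "assortativity", "mean_nodal_betweenness"):
            a, b = getattr(g1, f), getattr(g2, f)
            assert a == pytest.approx(b, nan_ok=True)
        n1, n2 = gm.nodal_metrics(adj), gm.nodal_metrics(padj)
        assert np.allclose(n1.degree[perm], n2.degree)
        assert np.allclose(n1.betweenness[perm], n2.betweenness)


class TestSmallWorld:
    def test_self_null_gives_unit_indices(self):
        # lattice ring with neighbour-of-neighbour edges (nonzero clustering)
        n = 12
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for step in (1, 2):
                j = (i + step) % n
                adj[i, j] = adj[j, i] = True
        c = float(gm.clustering_coefficients(adj).mean())
        l = gm.char_path_length(adj)
        ens = gm.NullEnsemble(n_null=5, c_null=np.full(5, c), l_null=np.full(5, l))
        gamma, lam, sigma = gm.small_world_normalize(adj, ens)
        assert (gamma, lam, sigma) == (pytest.approx(1.0),) * 3

    def test_random_graph_sigma_near_one(self):
        rng = np.random.default_rng(0)
        adj = oracle.random_graph(20, 0.4, rng)
        ens = gm.null_ensemble(adj, n_null=100, rng=rng)
        gamma, lam, sigma = gm.small_world_normalize(adj, ens)
        assert abs(sigma - 1.0) < 0.15

    def test_lattice_ring_is_small_world_contrast(self):
        """A ring lattice with neighbour-of-neighbour edges: gamma >> 1."""
        n = 20
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for step in (1, 2):
                j = (i + step) % n
                adj[i, j] = adj[j, i] = True
        ens = gm.null_ensemble(adj, n_null=50, rng=1)
        gamma, lam, _ = gm.small_world_normalize(adj, ens)
        assert gamma > 1.5
        assert lam > 1.0

    def test_null_graphs_preserve_degree_sequence(self):
        rng = np.random.default_rng(3)
        adj = oracle.random_graph(15, 0.3, rng)
        G = nx.from_numpy_array(adj.astype(int))
        H = G.copy()
        nx.double_edge_swap(H, nswap=10 * G.number_of_edges(),
                            max_tries=2000, seed=4)
        assert sorted(d for _, d in H.degree()) == sorted(d for _, d in G.degree())


class TestAUC:
    def test_constant_curve_returns_constant(self):
        grid = np.linspace(0.1, 0.5, 41)
        assert gm.auc_over_densities(np.full(41, 3.7), grid) == pytest.approx(3.7)

    def test_linear_curve_returns_midpoint(self):
        grid = np.linspace(0.1, 0.5, 41)
        vals = np.linspace(2.0, 6.0, 41)
        assert gm.auc_over_densities(vals, grid) == pytest.approx(4.0)

    def test_matches_trapezoid_oracle_on_random_curves(self, rng):
        grid = np.sort(rng.uniform(0.1, 0.5, 17))
        vals = rng.normal(0, 1, 17)
        assert gm.auc_over_densities(vals, grid) == pytest.approx(
            oracle.trapezoid_average(vals.tolist(), grid.tolist()), abs=1e-12)

    def test_non_finite_points_excluded(self):
        grid = np.array([0.1, 0.2, 0.3, 0.4])
        vals = np.array([np.nan, 2.0, 2.0, np.nan])
        assert gm.auc_over_densities(vals, grid) == pytest.approx(2.0)
        assert np.isnan(gm.auc_over_densities(np.full(4, np.nan), grid))

    def test_efficiency_monotone_along_nested_sweep(self, hc_network):
        import motorscn as m
        grid = m.RunConfig().density_grid
        sweep = m.sweep_densities(hc_network, grid)
        eff = [gm.global_efficiency(sweep.graphs[k]) for k in range(41)]
        assert all(b >= a - 1e-12 for a, b in zip(eff, eff[1:]))
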