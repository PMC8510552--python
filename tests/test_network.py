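import networkx as nx
import numpy as np
import pandas as pd
import pytest

from assemblage import (CoNetwork, CorrelationResult, OtuTable,
                        balanced_subsample, bh_adjust, build_network,
                        detect_modules, node_roles, per_sample_subnetworks,
                        solve_basis_variances, solve_basis_variances_exact,
                        sparcc, topology_summary)
from assemblage.io import SampleMetadata
from assemblage.network import correlations_from_basis, variation_matrix


def make_corr_result(rho: pd.DataFrame, padj: pd.DataFrame | None):
    return CorrelationResult(correlations=rho, p_values=padj,
                             p_adjusted=padj, n_iterations=1,
                             excluded_pairs=[])


class TestBasisSolver:
    def test_three_component_hand_system(self):
        # t_12=5, t_13=10, t_23=13 under zero basis correlation
        t = np.array([[0.0, 5.0, 10.0],
                      [5.0, 0.0, 13.0],
                      [13.0, 13.0, 0.0]])
        t[1, 2] = t[2, 1] = 13.0
        t[0, 2] = t[2, 0] = 10.0
        w = solve_basis_variances_exact(t)
        np.testing.assert_allclose(w, [1.0, 4.0, 9.0])
        rho = correlations_from_basis(t, w)
        off = rho[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_linear_system_recovers_uncorrelated_basis(self):
        # t_ij = w_i + w_j corresponds to rho = 0 everywhere
        w_true = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t = w_true[:, None] + w_true[None, :]
        np.fill_diagonal(t, 0.0)
        w = solve_basis_variances(t)
        np.testing.assert_allclose(w, w_true, atol=1e-9)


class TestSparcc:
    @staticmethod
    def _lognormal_counts(rng, n_samples, n_otus, depth=5000):
        absolute = rng.lognormal(0, 1, size=(n_samples, n_otus))
        frac = absolute / absolute.sum(axis=1, keepdims=True)
        return np.stack([rng.multinomial(depth, f) for f in frac])

    def test_independent_components_near_zero(self):
        # independent log-normal absolute abundances: SparCC suppresses the
        # compositional artifact that biases Pearson on proportions, and the
        # residual mean |rho| stays small as the number of components grows
        means = {}
        for d in (5, 10, 40):
            rng = np.random.default_rng(0)
            absolute = rng.lognormal(0, 2.0, size=(200, d))
            frac = absolute / absolute.sum(axis=1, keepdims=True)
            counts = np.stack([rng.multinomial(5000, f) for f in frac])
            table = OtuTable(pd.DataFrame(
                counts, index=[f"s{i}" for i in range(200)],
                columns=[f"o{j}" for j in range(d)]))
            res = sparcc(table, n_iter=5, n_bootstrap=0, seed=1)
            off = ~np.eye(d, dtype=bool)
            means[d] = np.abs(res.correlations.to_numpy()[off]).mean()
            prop = counts / counts.sum(axis=1, keepdims=True)
            pear = np.corrcoef(prop, rowvar=False)
            mean_abs_pearson = np.abs(pear[off]).mean()
            assert means[d] < 0.1
            if d <= 10:  # where the closure bias is substantial
                assert means[d] < mean_abs_pearson / 1.5

    def test_covarying_pair_detected(self):
        rng = np.random.default_rng(2)
        n, d = 80, 12
        base = rng.lognormal(0, 1, size=(n, d))
        shared = rng.lognormal(0, 1.5, size=n)
        base[:, 0] = shared
        base[:, 1] = shared * 2.0  # perfectly covarying absolute abundances
        frac = base / base.sum(axis=1, keepdims=True)
        counts = np.stack([rng.multinomial(20000, f) for f in frac])
        table = OtuTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(n)],
            columns=[f"o{j}" for j in range(d)]))
        res = sparcc(table, n_iter=5, n_bootstrap=0, seed=3)
        assert res.correlations.iloc[0, 1] > 0.8

    def test_compositional_scale_invariance(self):
        rng = np.random.default_rng(4)
        counts = self._lognormal_counts(rng, 40, 15, depth=3000)
        table = OtuTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(40)],
            columns=[f"o{j}" for j in range(15)]))
        scaled = OtuTable(table.data * 7)  # per-sample constant rescaling
        r1 = sparcc(table, n_iter=5, n_bootstrap=0, seed=5).correlations
        r2 = sparcc(scaled, n_iter=5, n_bootstrap=0, seed=5).correlations
        delta = np.abs(r1.to_numpy() - r2.to_numpy())
        assert delta[~np.eye(15, dtype=bool)].mean() < 0.05

    def test_needs_four_otus(self):
        df = pd.DataFrame(np.ones((5, 3), dtype=int),
                          index=[f"s{i}" for i in range(5)],
                          columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            sparcc(OtuTable(df))

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(6)
        counts = self._lognormal_counts(rng, 30, 10, depth=2000)
        table = OtuTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(30)],
            columns=[f"o{j}" for j in range(10)]))
        rho = sparcc(table, n_iter=4, n_bootstrap=0, seed=7).correlations
        m = rho.to_numpy()
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert np.abs(m).max() <= 1.0 + 1e-12


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_hand_computation(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adj, expected, atol=1e-12)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestBuildNetwork:
    @staticmethod
    def _corr3(r_ab, p_ab):
        ids = ["a", "b", "c"]
        rho = pd.DataFrame(np.eye(3), index=ids, columns=ids)
        rho.loc["a", "b"] = rho.loc["b", "a"] = r_ab
        padj = pd.DataFrame(np.ones((3, 3)) - np.eye(3), index=ids,
                            columns=ids)
        padj.loc["a", "b"] = padj.loc["b", "a"] = p_ab
        return make_corr_result(rho, padj)

    def test_boundary_r_inclusive(self):
        net = build_network(self._corr3(0.7, 0.005))
        assert net.n_edges == 1

    def test_significant_but_weak_rejected(self):
        with pytest.warns(UserWarning):
            net = build_network(self._corr3(0.69, 0.001))
        assert net.n_edges == 0

    def test_strong_but_nonsignificant_rejected(self):
        with pytest.warns(UserWarning):
            net = build_network(self._corr3(0.9, 0.02))
        assert net.n_edges == 0

    def test_complete_graph(self):
        k = 5
        ids = [f"o{i}" for i in range(k)]
        rho = pd.DataFrame(np.ones((k, k)), index=ids, columns=ids)
        padj = pd.DataFrame(np.zeros((k, k)), index=ids, columns=ids)
        net = build_network(make_corr_result(rho, padj))
        assert net.n_edges == k * (k - 1) // 2

    def test_monotone_in_r_min(self, rng):
        k = 8
        ids = [f"o{i}" for i in range(k)]
        m = rng.uniform(-1, 1, size=(k, k))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        rho = pd.DataFrame(m, index=ids, columns=ids)
        padj = pd.DataFrame(np.zeros((k, k)), index=ids, columns=ids)
        prev = np.inf
        import warnings
        for r_min in (0.2, 0.4, 0.6, 0.8):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                e = build_network(make_corr_result(rho, padj), r_min=r_min).n_edges
            assert e <= prev
            prev = e


class TestBalancedSubsample:
    def test_paper_sizes(self):
        rows = []
        for i in range(30):
            rows.append(("near" + str(i), "nearshore"))
        for i in range(24):
            rows.append(("off" + str(i), "offshore"))
        df = pd.DataFrame({
            "station": "A", "habitat_class": [h for _, h in rows],
            "layer": "surface", "latitude": 20.0, "longitude": 110.0,
            "depth": 5.0, "temperature": 25.0},
            index=[s for s, _ in rows])
        md = SampleMetadata(df)
        picked = balanced_subsample(md, "habitat_class", 24, seed=0)
        counts = pd.Series([df.loc[s, "habitat_class"] for s in picked]).value_counts()
        assert counts["nearshore"] == 24 and counts["offshore"] == 24

    def test_whole_group_when_exact(self, tiny_metadata):
        picked = balanced_subsample(tiny_metadata, "habitat_class", 2, seed=1)
        assert sorted(picked) == ["a1", "a2", "b1", "b2"]

    def test_seed_changes_selection(self):
        df = pd.DataFrame({
            "station": "A", "habitat_class": ["nearshore"] * 20,
            "layer": "surface", "latitude": 20.0, "longitude": 110.0,
            "depth": 5.0, "temperature": 25.0},
            index=[f"s{i}" for i in range(20)])
        md = SampleMetadata(df)
        a = balanced_subsample(md, "habitat_class", 10, seed=1)
        b = balanced_subsample(md, "habitat_class", 10, seed=2)
        assert len(a) == len(b) == 10
        assert a != b

    def test_insufficient_samples(self, tiny_metadata):
        with pytest.raises(ValueError):
            balanced_subsample(tiny_metadata, "habitat_class", 3)


class TestTopology:
    def test_triangle(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        for u, v in g.edges:
            g[u][v]["sign"] = 1
        summ = topology_summary(CoNetwork(graph=g))
        assert summ.average_clustering == pytest.approx(1.0)
        assert summ.diameter == 1
        assert summ.density == pytest.approx(1.0)
        assert summ.ppe == 100.0 and summ.pne == 0.0

    def test_path_graph_assortativity_brute_force(self):
        g = nx.path_graph(4)
        summ = topology_summary(CoNetwork(graph=g))
        # brute-force Pearson over the 6 directed edge endpoint degrees
        deg = dict(g.degree)
        xs, ys = [], []
        for u, v in g.edges:
            xs += [deg[u], deg[v]]
            ys += [deg[v], deg[u]]
        expected = np.corrcoef(xs, ys)[0, 1]
        assert expected == pytest.approx(-0.5)
        assert summ.degree_assortativity == pytest.approx(-0.5)

    def test_identities_on_random_graph(self, rng):
        g = nx.gnm_random_graph(30, 60, seed=3)
        summ = topology_summary(CoNetwork(graph=g))
        assert summ.average_degree == pytest.approx(2 * 60 / 30)
        assert summ.density == pytest.approx(2 * 60 / (30 * 29))
        assert summ.ppe + summ.pne == pytest.approx(100.0)

    def test_table2_consistency_nearshore(self):
        g = nx.gnm_random_graph(495, 3749, seed=0)
        summ = topology_summary(CoNetwork(graph=g))
        assert round(summ.average_degree, 3) == 15.147
        assert round(summ.density, 3) == 0.031

    def test_single_node(self):
        g = nx.Graph()
        g.add_node("a")
        summ = topology_summary(CoNetwork(graph=g))
        assert np.isnan(summ.diameter)
        assert np.isnan(summ.average_path_length)


class TestModules:
    def test_two_triangles_q_half(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                      ("x", "y"), ("y", "z"), ("x", "z")])
        net = CoNetwork(graph=g)
        modules, q = detect_modules(net, seed=0)
        assert q == pytest.approx(0.5)
        assert modules["a"] == modules["b"] == modules["c"]
        assert modules["x"] == modules["y"] == modules["z"]
        assert modules["a"] != modules["x"]

    def test_complete_graph_near_zero(self):
        g = nx.complete_graph(8)
        _, q = detect_modules(CoNetwork(graph=g), seed=0)
        assert q == pytest.approx(0.0, abs=1e-9)

    def test_relabel_invariance(self):
        g1 = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                       ("x", "y"), ("y", "z"), ("x", "z"), ("c", "x")])
        mapping = {n: n.upper() for n in g1.nodes}
        g2 = nx.relabel_nodes(g1, mapping)
        _, q1 = detect_modules(CoNetwork(graph=g1), seed=5)
        _, q2 = detect_modules(CoNetwork(graph=g2), seed=5)
        assert q1 == pytest.approx(q2)


class TestNodeRoles:
    def test_intramodular_c_zero(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        net = CoNetwork(graph=g)
        roles = node_roles(net, modules={"a": 0, "b": 0, "c": 0})
        assert (roles.table["c"] == 0.0).all()

    def test_even_split_c_half(self):
        g = nx.Graph([("hub", "a"), ("hub", "b")])
        modules = {"hub": 0, "a": 0, "b": 1}
        roles = node_roles(CoNetwork(graph=g), modules=modules)
        assert roles.table.loc["hub", "c"] == pytest.approx(0.5)

    def test_three_one_split(self):
        g = nx.Graph([("n", "a1"), ("n", "a2"), ("n", "a3"), ("n", "b1")])
        modules = {"n": 0, "a1": 0, "a2": 0, "a3": 0, "b1": 1}
        roles = node_roles(CoNetwork(graph=g), modules=modules)
        assert roles.table.loc["n", "c"] == pytest.approx(0.375)

    def test_categories_partition(self, rng):
        g = nx.gnm_random_graph(40, 120, seed=9)
        g = nx.relabel_nodes(g, {n: f"o{n}" for n in g.nodes})
        net = CoNetwork(graph=g)
        detect_modules(net, seed=0)
        roles = node_roles(net)
        cats = set(roles.table["category"])
        assert cats <= {"network hub", "module hub", "connector",
                        "peripheral"}
        assert len(roles.table) == 40
        # quadrant partition is exact
        for _, row in roles.table.iterrows():
            if row["z"] > 2.5:
                expected = "network hub" if row["c"] > 0.6 else "module hub"
            else:
                expected = "connector" if row["c"] > 0.6 else "peripheral"
            assert row["category"] == expected

    def test_c_upper_bound(self):
        # node linked once to each of 4 modules: c = 1 - 1/4
        g = nx.Graph([("n", "a"), ("n", "b"), ("n", "c"), ("n", "d")])
        modules = {"n": 0, "a": 0, "b": 1, "c": 2, "d": 3}
        roles = node_roles(CoNetwork(graph=g), modules=modules)
        assert roles.table.loc["n", "c"] == pytest.approx(1 - 1 / 4)


class TestPerSampleSubnetworks:
    @staticmethod
    def _net_and_table():
        g = nx.Graph([("o1", "o2"), ("o2", "o3"), ("o3", "o4")])
        net = CoNetwork(graph=g)
        df = pd.DataFrame(
            [[5, 5, 5, 5], [5, 5, 0, 0], [0, 0, 0, 0]],
            index=["all", "half", "none"],
            columns=["o1", "o2", "o3", "o4"])
        return net, OtuTable(df)

    def test_full_sample_is_full_network(self):
        net, table = self._net_and_table()
        df, _ = per_sample_subnetworks(net, table)
        assert df.loc["all", "n_nodes"] == 4
        assert df.loc["all", "n_edges"] == 3

    def test_empty_sample_missing(self):
        net, table = self._net_and_table()
        df, _ = per_sample_subnetworks(net, table)
        assert np.isnan(df.loc["none", "n_nodes"])

    def test_induced_subgraph_bound(self):
        net, table = self._net_and_table()
        df, _ = per_sample_subnetworks(net, table)
        assert (df["n_nodes"].dropna() <= net.n_nodes).all()
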