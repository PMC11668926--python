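import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.stats import spearmanr

from asvkit.core_io import AsvTable
from asvkit.cooccurrence import (
    DegreeFit,
    er_null_ensemble,
    fit_degree_distribution,
    keystones,
    o_r_ratios,
    prevalence_filter,
    spearman_correlations,
    spearman_edges,
    topology,
)


def table_from_columns(cols: dict[str, list]) -> AsvTable:
    ids = list(cols)
    mat = np.array([cols[a] for a in ids]).T
    return AsvTable([f"s{i}" for i in range(mat.shape[0])], ids, mat)


class TestPrevalenceFilter:
    def test_twenty_percent_kept(self):
        col = [1] * 10 + [0] * 38  # 10 of 48 = 20.8%
        t = table_from_columns({"keep": col, "anchor": [1] * 48})
        assert "keep" in prevalence_filter(t, 0.20).asv_ids

    def test_below_twenty_percent_dropped(self):
        col = [1] * 9 + [0] * 39  # 18.75%
        t = table_from_columns({"drop": col, "anchor": [1] * 48})
        assert "drop" not in prevalence_filter(t, 0.20).asv_ids

    def test_zero_threshold_identity(self, small_table):
        out = prevalence_filter(small_table, 0.0)
        assert out.asv_ids == small_table.asv_ids


class TestSpearmanEdges:
    def test_monotone_pair_rho_one(self):
        t = table_from_columns({"a": [1, 2, 3, 4, 5], "b": [2, 4, 9, 16, 30]})
        rho, _ = spearman_correlations(t.counts)
        assert rho[0, 1] == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        t = table_from_columns({"a": [1, 2, 3, 4, 5], "b": [9, 7, 5, 3, 1]})
        rho, _ = spearman_correlations(t.counts)
        assert rho[0, 1] == pytest.approx(-1.0)

    def test_hand_example_point_eight(self):
        t = table_from_columns({"a": [1, 2, 3, 4, 5], "b": [2, 1, 4, 3, 5]})
        rho, _ = spearman_correlations(t.counts)
        assert rho[0, 1] == pytest.approx(0.8)

    def test_matches_scipy_oracle(self, rng):
        counts = rng.integers(0, 40, size=(12, 6))
        rho, p = spearman_correlations(counts)
        for i in range(6):
            for j in range(i + 1, 6):
                sp = spearmanr(counts[:, i], counts[:, j])
                assert rho[i, j] == pytest.approx(sp.statistic, abs=1e-12)
                assert p[i, j] == pytest.approx(sp.pvalue, abs=1e-9)

    def test_every_edge_satisfies_thresholds(self, rng):
        counts = rng.integers(0, 60, size=(15, 20))
        t = AsvTable([f"s{i}" for i in range(15)],
                     [f"t{j}" for j in range(20)], counts)
        net = spearman_edges(t, rho_min=0.5, alpha=0.05)
        for _, row in net.edges_frame().iterrows():
            sp = spearmanr(
                counts[:, t.asv_ids.index(row.node1)],
                counts[:, t.asv_ids.index(row.node2)],
            )
            assert sp.statistic > 0.5
            assert sp.pvalue < 0.05

    def test_zero_variance_excluded(self):
        t = table_from_columns(
            {"flat": [3, 3, 3, 3, 3], "a": [1, 2, 3, 4, 5], "b": [1, 2, 3, 4, 5]}
        )
        net = spearman_edges(t, rho_min=0.5, alpha=0.05)
        assert "flat" not in net.nodes

    def test_too_few_samples_rejected(self):
        t = table_from_columns({"a": [1, 2, 3], "b": [1, 2, 3]})
        with pytest.raises(ValueError):
            spearman_edges(t)


def _betweenness_oracle(g: nx.Graph) -> dict:
    """Brute-force all-pairs shortest-path enumeration."""
    nodes = list(g.nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(1 for p in paths if v in p) / len(paths)
            bc[v] += frac
    return bc


class TestTopology:
    def test_path_graph(self):
        g = nx.path_graph(["A", "B", "C"])
        topo = topology(g)
        assert topo.loc["B", "betweenness"] == pytest.approx(1.0)
        assert topo.loc["A", "betweenness"] == pytest.approx(0.0)

    def test_star_hub_degree(self):
        g = nx.star_graph(7)  # hub 0 with 7 leaves
        topo = topology(g)
        assert topo.loc[0, "degree"] == 7

    def test_complete_graph_zero_betweenness(self):
        topo = topology(nx.complete_graph(5))
        assert (topo["betweenness"] == 0).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_oracle(self, seed):
        g = nx.gnm_random_graph(10, 16, seed=seed)
        topo = topology(g)
        oracle = _betweenness_oracle(g)
        for v in g.nodes:
            assert topo.loc[v, "betweenness"] == pytest.approx(oracle[v], abs=1e-9)

    def test_isolated_node_closeness_zero(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("lonely")
        topo = topology(g)
        assert topo.loc["lonely", "closeness"] == 0.0
        assert ((topo["closeness"] >= 0) & (topo["closeness"] <= 1)).all()


class TestErEnsemble:
    def test_handshake_lemma(self):
        ens = er_null_ensemble(30, 55, reps=10, seed=1)
        degs = ens.degree_sequences()
        assert (degs.sum(axis=1) == 110).all()

    def test_edges_are_simple_and_unique(self):
        ens = er_null_ensemble(12, 40, reps=5, seed=2)
        for r in range(5):
            pairs = set(zip(ens.edges_i[r], ens.edges_j[r]))
            assert len(pairs) == 40
            assert all(i < j for i, j in pairs)
            assert all(0 <= i and j < 12 for i, j in pairs)

    def test_mean_degree_at_network_scale(self):
        ens = er_null_ensemble(1212, 20655, reps=2, seed=3)
        mean_deg = ens.degree_sequences().mean()
        assert mean_deg == pytest.approx(2 * 20655 / 1212)
        assert mean_deg == pytest.approx(34.08, abs=0.01)

    def test_determinism(self):
        a = er_null_ensemble(20, 30, reps=3, seed=9)
        b = er_null_ensemble(20, 30, reps=3, seed=9)
        np.testing.assert_array_equal(a.edges_i, b.edges_i)
        np.testing.assert_array_equal(a.edges_j, b.edges_j)

    def test_infeasible_edge_count(self):
        with pytest.raises(ValueError):
            er_null_ensemble(5, 11, reps=1, seed=0)


class TestDegreeFits:
    def test_exact_power_law_recovered(self):
        # freq = 1200 * k^-1 exactly, at degrees where that is an integer
        ks = np.array([1, 2, 4, 5, 8, 10, 16, 20])
        freq = 1200 // ks
        degrees = np.repeat(ks, freq)
        fit = fit_degree_distribution(degrees, "power_law")
        assert fit.adjusted_r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.parameters["exponent"] == pytest.approx(-1.0, abs=1e-9)

    def test_exact_gaussian_recovered(self):
        ks = np.arange(5, 40)
        freq = np.round(200 * np.exp(-((ks - 20) ** 2) / (2 * 5.0**2))).astype(int)
        degrees = np.repeat(ks, freq)
        fit = fit_degree_distribution(degrees, "gaussian")
        assert fit.adjusted_r_squared == pytest.approx(1.0, abs=1e-3)
        assert fit.parameters["mu"] == pytest.approx(20, abs=0.2)

    def test_er_graph_gaussian_beats_power_law(self):
        ens = er_null_ensemble(1212, 20655, reps=1, seed=0)
        degs = ens.degree_sequences()[0]
        gauss = fit_degree_distribution(degs, "gaussian")
        power = fit_degree_distribution(degs, "power_law")
        assert gauss.adjusted_r_squared > 0.9
        assert gauss.adjusted_r_squared > power.adjusted_r_squared

    def test_er_ensemble_mean_spectrum_gaussian(self):
        # fitting the ensemble-averaged spectrum reproduces the ~0.98 quality
        ens = er_null_ensemble(1212, 20655, reps=20, seed=0)
        fit = fit_degree_distribution(ens.mean_spectrum(), "gaussian")
        assert fit.adjusted_r_squared >= 0.98

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            fit_degree_distribution(np.array([1, 1, 2]), "gaussian")


class TestKeystones:
    def test_criteria(self):
        import pandas as pd

        topo = pd.DataFrame(
            {
                "degree": [150.0, 90.0, 150.0],
                "betweenness": [1000.0, 10.0, 6000.0],
                "closeness": [0.5, 0.5, 0.5],
            },
            index=["yes", "low_degree", "high_betweenness"],
        )
        assert keystones(topo) == ["yes"]


class TestORRatios:
    def _net(self, edges, nodes):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        from asvkit.cooccurrence import CooccurrenceNetwork

        return CooccurrenceNetwork(g, 0.8, 0.01)

    def test_single_label_ratio_one(self):
        nodes = [f"n{i}" for i in range(10)]
        edges = [(nodes[i], nodes[i + 1]) for i in range(9)]
        net = self._net(edges, nodes)
        ens = er_null_ensemble(10, 9, reps=50, seed=1)
        out = o_r_ratios(net, {v: "all" for v in nodes}, ens)
        assert len(out) == 1
        assert out["observed"].iloc[0] == 9
        assert out["o_r_ratio"].iloc[0] == pytest.approx(1.0)

    def test_zero_observed_ratio_zero(self):
        nodes = ["a1", "a2", "b1", "b2"]
        net = self._net([("a1", "a2"), ("b1", "b2")], nodes)
        ens = er_null_ensemble(4, 2, reps=200, seed=2)
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        out = o_r_ratios(net, groups, ens).set_index(["group1", "group2"])
        assert out.loc[("A", "B"), "observed"] == 0
        assert out.loc[("A", "B"), "o_r_ratio"] == 0.0

    def test_observed_partition_sums_to_edge_count(self, rng):
        nodes = [f"n{i}" for i in range(12)]
        g = nx.gnm_random_graph(12, 20, seed=5)
        edges = [(nodes[u], nodes[v]) for u, v in g.edges]
        net = self._net(edges, nodes)
        groups = {v: rng.choice(["x", "y", "z"]) for v in nodes}
        ens = er_null_ensemble(12, 20, reps=20, seed=3)
        out = o_r_ratios(net, groups, ens)
        assert out["observed"].sum() == 20
        assert out["o_percent"].sum() == pytest.approx(100.0)
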