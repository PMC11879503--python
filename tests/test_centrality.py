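"""Node/bridge centrality and predictability against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from netpsych.centrality import (
    bridge_centralities,
    centrality_table,
    node_centralities,
    predictability,
    select_bridge_nodes,
    tidy_table,
)
from netpsych.datasets import QuestionnaireDataset
from netpsych.ggm import WeightedNetwork
from netpsych.simulate import PrecisionSpec, build_precision, sample_copula

from ._oracles import brute_bridge, brute_centralities
from .conftest import random_network


class TestNodeCentrality:
    def test_definitional_sums(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.3
        W[0, 2] = W[2, 0] = -0.2
        net = WeightedNetwork(W, ["a", "b", "c"])
        t = node_centralities(net)
        assert t.loc["a", "strength"] == pytest.approx(0.5)
        assert t.loc["a", "expected_influence"] == pytest.approx(0.1)

    def test_chain_hand_enumeration(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5  # d = 2
        W[1, 2] = W[2, 1] = 0.25  # d = 4
        net = WeightedNetwork(W, ["A", "B", "C"])
        t = node_centralities(net)
        assert t.loc["B", "closeness"] == pytest.approx(1 / 6)
        assert t.loc["B", "betweenness"] == pytest.approx(1.0)
        assert t.loc["A", "betweenness"] == 0 and t.loc["C", "betweenness"] == 0

    def test_handshake_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            net = random_network(rng, 7)
            t = node_centralities(net)
            total = np.abs(net.W[np.triu_indices(7, 1)]).sum()
            assert t["strength"].sum() == pytest.approx(2 * total)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            p = int(rng.integers(6, 9))
            net = random_network(rng, p)
            t = node_centralities(net)
            s, c, b, e = brute_centralities(net.W)
            assert np.allclose(t["strength"], s)
            assert np.allclose(t["closeness"], c)
            assert np.allclose(t["betweenness"], b, atol=1e-9)
            assert np.allclose(t["expected_influence"], e)

    def test_strength_dominates_ei_with_equality_iff_nonnegative(self):
        rng = np.random.default_rng(5)
        net = random_network(rng, 6)
        t = node_centralities(net)
        assert (t["strength"] >= t["expected_influence"].abs() - 1e-12).all()
        pos = WeightedNetwork(np.abs(net.W), net.node_names)
        tp = node_centralities(pos)
        assert np.allclose(tp["strength"], tp["expected_influence"])

    def test_scaling_behaviour(self):
        rng = np.random.default_rng(6)
        net = random_network(rng, 6, density=0.8)
        scaled = WeightedNetwork(0.5 * net.W, net.node_names)
        t1, t2 = node_centralities(net), node_centralities(scaled)
        assert np.allclose(t2["strength"], 0.5 * t1["strength"])
        assert np.allclose(t2["expected_influence"], 0.5 * t1["expected_influence"])
        assert np.allclose(t2["closeness"], 0.5 * t1["closeness"])
        assert np.allclose(t2["betweenness"], t1["betweenness"])

    def test_disconnected_closeness_uses_reachable(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        net = WeightedNetwork(W, list("abcd"))
        t = node_centralities(net)
        assert t.loc["a", "closeness"] == pytest.approx(0.5)
        assert t.loc["a", "n_reachable"] == 1
        assert t.loc["c", "closeness"] == 0.0


class TestPredictability:
    def test_independent_columns_near_zero(self):
        ds = sample_copula(5000, np.eye(5), None, seed=1)
        assert (predictability(ds) < 0.02).all()

    def test_exact_linear_combination(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=500), rng.normal(size=500)
        ds = QuestionnaireDataset(pd.DataFrame({"a": a, "b": b, "c": a + 2 * b}))
        assert predictability(ds)["c"] == pytest.approx(1.0, abs=1e-10)

    def test_closed_form_from_precision(self):
        K = build_precision(PrecisionSpec(3, [(0, 1, 0.4), (1, 2, 0.3)], 0.0))
        Sigma = np.linalg.inv(K)
        ds = sample_copula(10000, K, None, seed=3)
        r2 = predictability(ds)
        for j in range(3):
            expect = 1 - 1 / (K[j, j] * Sigma[j, j])
            assert r2.iloc[j] == pytest.approx(expect, abs=0.02)

    def test_needs_enough_rows(self):
        ds = sample_copula(200, np.eye(3), None, seed=4)
        small = ds.subset(np.arange(4))
        with pytest.raises(ValueError, match="n > p"):
            predictability(small)


class TestBridgeCentrality:
    def test_single_cross_edge(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.4  # within community
        W[1, 2] = W[2, 1] = 0.11  # cross
        net = WeightedNetwork(W, ["a", "b", "c"], {"a": "X", "b": "X", "c": "Y"})
        t = bridge_centralities(net)
        assert t.loc["b", "bridge_strength"] == pytest.approx(0.11)
        assert t.loc["b", "bridge_expected_influence"] == pytest.approx(0.11)

    def test_all_within_community_edges(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.3
        W[2, 3] = W[3, 2] = 0.2
        net = WeightedNetwork(
            W, list("abcd"), {"a": "X", "b": "X", "c": "Y", "d": "Y"}
        )
        t = bridge_centralities(net)
        assert (t["bridge_strength"] == 0).all()

    def test_matches_brute_force_two_communities(self):
        rng = np.random.default_rng(20)
        comm_map = {f"n{i}": ("A" if i < 3 else "B") for i in range(6)}
        for _ in range(20):
            net = random_network(rng, 6, density=0.6, communities=comm_map)
            t = bridge_centralities(net)
            comm = [comm_map[n] for n in net.node_names]
            bs, bc, bb, be = brute_bridge(net.W, comm)
            assert np.allclose(t["bridge_strength"], bs)
            assert np.allclose(t["bridge_closeness"], bc)
            assert np.allclose(t["bridge_betweenness"], bb, atol=1e-9)
            assert np.allclose(t["bridge_expected_influence"], be)

    def test_singleton_community_bridge_equals_strength(self):
        rng = np.random.default_rng(21)
        comm_map = {f"n{i}": "A" for i in range(5)} | {"n5": "B"}
        net = random_network(rng, 6, density=0.8, communities=comm_map)
        t = bridge_centralities(net)
        nt = node_centralities(net)
        assert t.loc["n5", "bridge_strength"] == pytest.approx(
            nt.loc["n5", "strength"]
        )

    def test_single_community_fails(self):
        rng = np.random.default_rng(22)
        net = random_network(rng, 4, communities={f"n{i}": "A" for i in range(4)})
        with pytest.raises(ValueError, match="single community"):
            bridge_centralities(net)


class TestBridgeSelection:
    def _table(self, values):
        return pd.DataFrame(
            {"bridge_strength": values},
            index=pd.Index([f"n{i}" for i in range(len(values))], name="node"),
        )

    def test_at_most_two_of_eight(self):
        rng = np.random.default_rng(30)
        for _ in range(20):
            sel = select_bridge_nodes(self._table(rng.random(8)))
            assert len(sel["bridge_strength"]) <= 2

    def test_all_equal_selects_nothing(self):
        sel = select_bridge_nodes(self._table([0.4] * 8))
        assert sel["bridge_strength"] == []

    def test_dominant_node_selected(self):
        sel = select_bridge_nodes(self._table([0.1] * 7 + [2.0]))
        assert sel["bridge_strength"] == ["n7"]


class TestTableAssembly:
    def test_combined_table_and_z_scores(self, study_sample):
        from netpsych.ggm import estimate_network

        data, _ = study_sample
        net = estimate_network(data)
        table = centrality_table(net, data)
        assert {"strength", "bridge_strength", "predictability"} <= set(table.columns)
        assert table["predictability"].between(0, 1).all()
        z = table["z_strength"]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)
        tidy = tidy_table(table)
        assert set(tidy.columns) == {"node", "index", "raw_value", "z_value"}
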