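"""Gaussian-BIC scoring, hill climbing, CPDAGs and bootstrap consensus."""

import itertools

import numpy as np
import pytest

from netpsych.dag import (
    ArcStrengthTable,
    DagStructure,
    bic_g_score,
    bootstrap_arcs,
    consensus_network,
    cpdag,
    hill_climb,
)
from netpsych.simulate import DagSpec, sample_linear_dag

from ._oracles import all_3node_dags, skeleton_and_vstructures

COLLIDER = DagSpec(3, [(0, 2, 0.8), (1, 2, 0.8)])


def exhaustive_best_score(data):
    """Best Gaussian BIC over all 25 three-node DAGs (independent search)."""
    return max(
        bic_g_score(DagStructure(3, arcs), data) for arcs in all_3node_dags()
    )


class TestDagStructure:
    def test_rejects_cycles_self_loops(self):
        with pytest.raises(ValueError, match="cyclic"):
            DagStructure(3, {(0, 1), (1, 2), (2, 0)})
        with pytest.raises(ValueError, match="self-loop"):
            DagStructure(2, {(0, 0)})

    def test_parents_lookup(self):
        d = DagStructure(3, {(0, 2), (1, 2)})
        assert d.parents(2) == (0, 1)
        assert d.parents(0) == ()


class TestBicScore:
    def test_empty_dag_equals_univariate_bics(self):
        ds = sample_linear_dag(5000, DagSpec(3), seed=1)
        score = bic_g_score(DagStructure(3, frozenset()), ds)
        Z = ds.values()
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        n = len(Z)
        expected = 0.0
        for j in range(3):
            s2 = Z[:, j].var()  # MLE variance
            expected += -0.5 * n * (np.log(2 * np.pi * s2) + 1) - 1.0 * np.log(n)
        assert score == pytest.approx(expected, rel=1e-10)

    def test_true_parent_improves_score(self):
        wins = 0
        for seed in range(20):
            ds = sample_linear_dag(2000, DagSpec(2, [(0, 1, 1.0)]), seed=seed)
            s0 = bic_g_score(DagStructure(2, frozenset()), ds)
            s1 = bic_g_score(DagStructure(2, {(0, 1)}), ds)
            wins += s1 > s0
        assert wins == 20

    def test_decomposable_and_order_invariant(self):
        ds = sample_linear_dag(500, COLLIDER, seed=3)
        a = bic_g_score(DagStructure(3, {(0, 2), (1, 2)}), ds)
        b = bic_g_score(DagStructure(3, {(1, 2), (0, 2)}), ds)
        assert a == b

    def test_collinear_parents_named(self):
        import pandas as pd

        from netpsych.datasets import QuestionnaireDataset

        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        ds = QuestionnaireDataset(
            pd.DataFrame({"a": x, "b": 2 * x + 1e-14 * rng.normal(size=300),
                          "c": rng.normal(size=300)})
        )
        with pytest.raises(ValueError, match="collinear parents for node c"):
            bic_g_score(DagStructure(3, {(0, 2), (1, 2)}), ds)


class TestHillClimb:
    def test_matches_exhaustive_search_small(self):
        rng = np.random.default_rng(5)
        for rep in range(5):
            arcs = [(0, 1, rng.uniform(-1, 1)), (1, 2, rng.uniform(-1, 1))]
            ds = sample_linear_dag(500, DagSpec(3, arcs), seed=int(rng.integers(2**31)))
            dag, score = hill_climb(ds, seed=rep, return_score=True)
            assert score == pytest.approx(exhaustive_best_score(ds), rel=1e-12)

    def test_independent_data_yields_empty_dag(self):
        empties = 0
        for seed in range(20):
            ds = sample_linear_dag(2000, DagSpec(4), seed=700 + seed)
            dag = hill_climb(ds, seed=seed)
            empties += len(dag.arcs) == 0
        assert empties >= 18

    def test_collider_vstructure_recovered(self):
        hits = 0
        for seed in range(20):
            ds = sample_linear_dag(5000, COLLIDER, seed=800 + seed)
            cp = cpdag(hill_climb(ds, seed=seed))
            hits += {(0, 2), (1, 2)} <= set(cp.directed) and not cp.undirected
        assert hits >= 18

    def test_never_below_empty_dag_and_deterministic(self):
        ds = sample_linear_dag(400, COLLIDER, seed=9)
        empty = bic_g_score(DagStructure(3, frozenset()), ds)
        d1, s1 = hill_climb(ds, seed=3, return_score=True)
        d2, s2 = hill_climb(ds, seed=3, return_score=True)
        assert s1 >= empty
        assert d1.arcs == d2.arcs and s1 == s2


class TestCpdag:
    def test_chain_fully_undirected(self):
        cp = cpdag(DagStructure(3, {(0, 1), (1, 2)}))
        assert not cp.directed
        assert cp.undirected == frozenset(
            {frozenset({0, 1}), frozenset({1, 2})}
        )

    def test_collider_fully_directed(self):
        cp = cpdag(DagStructure(3, {(0, 2), (1, 2)}))
        assert cp.directed == frozenset({(0, 2), (1, 2)})
        assert not cp.undirected

    def test_equivalence_criterion_over_all_3node_dags(self):
        dags = all_3node_dags()
        assert len(dags) == 25
        reps = {}
        for arcs in dags:
            cp = cpdag(DagStructure(3, arcs))
            key = (cp.directed, cp.undirected)
            invariants = skeleton_and_vstructures(3, arcs)
            reps.setdefault(key, set()).add(invariants)
        # same CPDAG <=> same skeleton + v-structures
        assert all(len(v) == 1 for v in reps.values())
        assert len(reps) == len({skeleton_and_vstructures(3, a) for a in dags})

    def test_orientation_closure_idempotent(self):
        # rule 1 propagation: 0 -> 1 part of a collider, then 1 - 2 compelled
        dag = DagStructure(4, {(0, 1), (3, 1), (1, 2)})
        cp = cpdag(dag)
        assert (1, 2) in cp.directed  # otherwise a new v-structure would appear
        # re-running the closure on its own output changes nothing
        assert cpdag(dag) == cp


class TestBootstrapArcs:
    def test_strong_edge_high_presence(self):
        ds = sample_linear_dag(1000, DagSpec(2, [(0, 1, 1.0)]), seed=10)
        tab = bootstrap_arcs(ds, B=100, restarts=2, perturbations=5, seed=11)
        assert tab.presence[frozenset({0, 1})] >= 0.85

    def test_independent_nodes_low_presence(self):
        vals = []
        for seed in range(10):
            ds = sample_linear_dag(1000, DagSpec(2), seed=900 + seed)
            tab = bootstrap_arcs(ds, B=50, restarts=1, perturbations=3, seed=seed)
            vals.append(tab.presence.get(frozenset({0, 1}), 0.0))
        assert np.median(vals) <= 0.5

    def test_direction_frequencies_sum_to_one(self):
        ds = sample_linear_dag(600, COLLIDER, seed=12)
        tab = bootstrap_arcs(ds, B=40, restarts=2, perturbations=5, seed=13)
        frame = tab.to_frame()
        assert not frame.empty
        assert np.allclose(frame["direction_ij"] + frame["direction_ji"], 1.0)
        assert frame["direction_ij"].between(0, 1).all()
        assert frame["presence"].between(0, 1).all()


class TestConsensus:
    def _table(self, presence, direction):
        return ArcStrengthTable(
            ["a", "b"], 100, {frozenset({0, 1}): presence}, {(0, 1): direction}
        )

    def test_threshold_application(self):
        cons = consensus_network(self._table(0.90, 0.60))
        assert len(cons.arcs) == 1
        assert cons.arcs.iloc[0].parent == "a" and cons.arcs.iloc[0].child == "b"
        cons_rev = consensus_network(self._table(0.90, 0.40))
        assert cons_rev.arcs.iloc[0].parent == "b"

    def test_presence_just_below_threshold(self):
        assert consensus_network(self._table(0.84, 0.9)).arcs.empty
        relaxed = consensus_network(self._table(0.84, 0.9), edge_threshold=0.75)
        assert len(relaxed.arcs) == 1

    def test_exact_tie_kept_undirected_and_flagged(self):
        cons = consensus_network(self._table(0.95, 0.5))
        assert cons.arcs.empty
        assert len(cons.undirected_pairs) == 1

    def test_raising_threshold_never_adds_arcs(self):
        tab = self._table(0.86, 0.7)
        n_arcs = [
            len(consensus_network(tab, edge_threshold=t).arcs)
            for t in (0.5, 0.85, 0.9)
        ]
        assert all(a >= b for a, b in zip(n_arcs, n_arcs[1:]))

    def test_listing_covers_majority_pairs(self):
        cons = consensus_network(self._table(0.60, 0.55))
        assert len(cons.listing) == 1 and cons.arcs.empty
        dot = consensus_network(self._table(0.9, 0.9)).to_dot()
        assert '"a" -> "b"' in dot
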