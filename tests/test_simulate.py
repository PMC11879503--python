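"""Ground-truth construction and copula/SEM sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpsych.simulate import (
    DagSpec,
    MarginalSpec,
    PrecisionSpec,
    build_precision,
    grouped_dataset,
    partial_corr_from_precision,
    sample_copula,
    sample_linear_dag,
    study_like_dataset,
    table1_marginals,
)

from ._oracles import partial_corr_by_regression


class TestBuildPrecision:
    def test_two_node_partial_equals_marginal(self):
        K = build_precision(PrecisionSpec(2, [(0, 1, 0.5)]))
        assert np.allclose(K / K[0, 0], [[1, -0.5], [-0.5, 1]])
        # for p=2 the partial correlation equals the marginal correlation
        S = np.linalg.inv(K)
        r01 = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
        assert r01 == pytest.approx(0.5, abs=1e-12)

    def test_empty_edges_gives_identity(self):
        assert np.array_equal(build_precision(PrecisionSpec(3)), np.eye(3))

    def test_round_trip_without_inflation(self):
        rng = np.random.default_rng(1)
        pairs = [(i, j) for i in range(8) for j in range(i + 1, 8)]
        idx = rng.choice(len(pairs), 10, replace=False)
        edges = [
            (pairs[k][0], pairs[k][1], float(rng.uniform(-0.3, 0.3))) for k in idx
        ]
        K, info = build_precision(PrecisionSpec(8, edges, 0.0), return_info=True)
        assert info["inflation"] == 0.0
        P = partial_corr_from_precision(K)
        for i, j, rho in edges:
            assert P[i, j] == pytest.approx(rho, abs=1e-10)

    def test_infeasible_request_names_edges(self):
        # three mutually strong positive partials need off-diagonals -0.9,
        # whose matrix has eigenvalue 1 - 2*0.9 < 0; a tiny inflation step
        # cannot rescue it within the step budget
        edges = [(0, 1, 0.9), (0, 2, 0.9), (1, 2, 0.9)]
        spec = PrecisionSpec(3, edges, 1e-30)
        with pytest.raises(ValueError, match="infeasible"):
            build_precision(spec)

    def test_inflation_recorded_and_partials_shrink(self):
        edges = [(0, 1, 0.6), (0, 2, 0.6), (1, 2, 0.6)]
        K, info = build_precision(PrecisionSpec(3, edges), return_info=True)
        assert info["inflation"] > 0
        assert np.linalg.eigvalsh(K)[0] > 0
        assert all(abs(v) < 0.6 for v in info["achieved_partials"].values())


class TestPartialCorr:
    def test_hand_example(self):
        P = partial_corr_from_precision(np.array([[2.0, -1.0], [-1.0, 2.0]]))
        assert P[0, 1] == pytest.approx(0.5)

    def test_identity(self):
        assert np.array_equal(partial_corr_from_precision(np.eye(5)), np.zeros((5, 5)))

    def test_matches_regression_oracle(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(4, 4))
        K = A @ A.T + 4 * np.eye(4)
        P = partial_corr_from_precision(K)
        Sigma = np.linalg.inv(K)
        for i in range(4):
            for j in range(i + 1, 4):
                assert P[i, j] == pytest.approx(
                    partial_corr_by_regression(Sigma, i, j), abs=1e-10
                )

    def test_rejects_non_pd(self):
        with pytest.raises(ValueError, match="positive definite"):
            partial_corr_from_precision(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestCopula:
    def test_marginal_mean_and_bounds(self):
        spq_cp = table1_marginals()[0]
        ds = sample_copula(5000, np.eye(8), [spq_cp] + [None] * 7, seed=3)
        col = ds.scores[spq_cp.name]
        assert abs(col.mean() - 2.83) < 0.1
        assert col.min() >= 0 and col.max() <= 8
        assert (col == col.astype(int)).all()

    def test_spearman_matches_pearson_mapping(self):
        from scipy.stats import spearmanr

        K = build_precision(PrecisionSpec(2, [(0, 1, 0.5)]))
        ds = sample_copula(2000, K, None, seed=9)
        rho_s = spearmanr(ds.scores.iloc[:, 0], ds.scores.iloc[:, 1]).statistic
        implied_r = 0.5  # p=2: partial == marginal correlation
        expected = 6 / np.pi * np.arcsin(implied_r / 2)
        assert abs(rho_s - expected) < 0.05

    def test_seeded_determinism(self):
        K = build_precision(PrecisionSpec(3, [(0, 1, 0.3)]))
        a = sample_copula(500, K, table1_marginals()[:3], seed=11)
        b = sample_copula(500, K, table1_marginals()[:3], seed=11)
        assert a.scores.equals(b.scores)

    def test_small_n_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            sample_copula(20, np.eye(3), None, seed=0)

    def test_infeasible_marginal_rejected(self):
        with pytest.raises(ValueError, match="outside bounds"):
            MarginalSpec("bad", 0, 8, 9.5, 1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        lo=st.integers(-5, 5),
        width=st.integers(1, 30),
        frac=st.floats(0.05, 0.95),
        seed=st.integers(0, 2**20),
    )
    def test_bounds_respected_always(self, lo, width, frac, seed):
        m = MarginalSpec("x", lo, lo + width, lo + frac * width, 1.0)
        ds = sample_copula(200, np.eye(1), [m], seed=seed)
        col = ds.scores["x"]
        assert col.between(m.min_score, m.max_score).all()

    def test_latent_monotone_preserves_spearman_sign(self):
        from scipy.stats import spearmanr

        K = build_precision(PrecisionSpec(2, [(0, 1, -0.4)]))
        marg = table1_marginals()[:2]
        rng = np.random.default_rng(5)
        latent = sample_copula(10000, K, None, seed=15)
        observed = sample_copula(10000, K, marg, seed=15)
        r_lat = spearmanr(latent.scores.iloc[:, 0], latent.scores.iloc[:, 1]).statistic
        r_obs = spearmanr(
            observed.scores.iloc[:, 0], observed.scores.iloc[:, 1]
        ).statistic
        assert np.sign(r_lat) == np.sign(r_obs)
        assert abs(r_lat - r_obs) < 0.03


class TestLinearDag:
    def test_independent_nodes(self):
        ds = sample_linear_dag(10000, DagSpec(3), seed=1)
        R = np.corrcoef(ds.values(), rowvar=False)
        assert np.all(np.abs(R[~np.eye(3, dtype=bool)]) < 0.03)

    def test_single_arc_correlation(self):
        ds = sample_linear_dag(10000, DagSpec(2, [(0, 1, 1.0)]), seed=2)
        r = np.corrcoef(ds.values(), rowvar=False)[0, 1]
        assert abs(r - 1 / np.sqrt(2)) < 0.02

    def test_collider_induces_negative_partial(self):
        spec = DagSpec(3, [(0, 2, 1.0), (1, 2, 1.0)])
        ds = sample_linear_dag(10000, spec, seed=3)
        R = np.corrcoef(ds.values(), rowvar=False)
        assert abs(R[0, 1]) < 0.03  # marginally independent
        K = np.linalg.inv(np.cov(ds.values(), rowvar=False))
        partial = -K[0, 1] / np.sqrt(K[0, 0] * K[1, 1])
        assert partial == pytest.approx(-0.5, abs=0.03)

    def test_covariance_matches_closed_form(self):
        spec = DagSpec(4, [(0, 1, 0.8), (1, 2, 0.5), (0, 3, -0.6)], noise_sd=1.0)
        ds = sample_linear_dag(10000, spec, seed=4)
        emp = np.cov(ds.values(), rowvar=False)
        assert np.max(np.abs(emp - spec.implied_covariance())) < 0.1

    def test_cycle_rejected_with_cycle_named(self):
        with pytest.raises(ValueError, match="cycle"):
            DagSpec(3, [(0, 1, 1.0), (1, 2, 1.0), (2, 0, 1.0)])


class TestTable1Fixture:
    @pytest.mark.parametrize(
        "name, lo, hi, mean, sd",
        [
            ("SPQ.I", 0, 8, 2.39, 2.06),
            ("ERQ.R", 6, 30, 18.33, 6.72),
            ("DASS.D", 0, 21, 2.93, 3.89),
        ],
    )
    def test_study_rows(self, name, lo, hi, mean, sd):
        spec = {m.name: m for m in table1_marginals()}[name]
        assert (spec.min_score, spec.max_score) == (lo, hi)
        assert spec.mean == mean and spec.sd == sd

    def test_communities_cover_three_instruments(self):
        from netpsych.simulate import STUDY_COMMUNITIES

        assert set(STUDY_COMMUNITIES.values()) == {"SPQ", "ERQ", "DASS"}
        assert len(STUDY_COMMUNITIES) == 8


class TestGroupedDataset:
    def test_labels_do_not_alter_pooled_scores(self):
        base = PrecisionSpec(4, [(0, 1, 0.3)])
        ds = grouped_dataset({"a": 100, "b": 100}, base, seed=6)
        pooled = np.sort(ds.values(), axis=0)
        relabeled = ds.groups.iloc[::-1].reset_index(drop=True)
        assert np.array_equal(pooled, np.sort(ds.values(), axis=0))
        assert len(relabeled) == ds.n

    def test_delta_edges_change_one_group_only(self):
        base = PrecisionSpec(3, [(0, 1, 0.0)][:0])
        ds = grouped_dataset(
            {"a": 4000, "b": 4000},
            PrecisionSpec(3),
            {"b": [(0, 1, 0.5)]},
            seed=8,
        )
        parts = ds.split_by("group")
        ra = np.corrcoef(parts["a"].values(), rowvar=False)[0, 1]
        rb = np.corrcoef(parts["b"].values(), rowvar=False)[0, 1]
        assert abs(ra) < 0.05
        assert rb > 0.4

    def test_study_like_dataset_shape_and_groups(self):
        ds = study_like_dataset(600, seed=10)
        assert ds.p == 8 and ds.n == 600
        assert set(ds.groups.columns) >= {"gender", "age", "age_band"}
        assert set(ds.groups["age_band"]) == {"9-10", "11-12"}
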