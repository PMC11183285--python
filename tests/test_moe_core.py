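"""Mixture-of-experts core: objective arithmetic, exact block updates,
alternating-descent monotonicity, validity indices, model selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moe_subtyper import (
    DeadExpertError,
    LabeledDataset,
    MOEConfig,
    bezdek_pc,
    cross_validate,
    fit_moe,
    grid_search_select,
    init_memberships,
    load_model,
    moe_objective,
    pairwise_wr,
    predict_label,
    save_model,
    update_centroids,
    update_experts,
    update_memberships,
)
from moe_subtyper.moe_core import ExpertModel, MOEModel, _simplex_qp_rows, _weighted_l1_fit

from conftest import separable_dataset
from oracles import expert_objective, simplex_qp_oracle, weighted_l1_oracle


def make_model(experts, memberships, config):
    return MOEModel(
        experts=experts, memberships=np.asarray(memberships, float),
        objective_trace=[0.0], converged=True, config=config,
        ad_ids=tuple(f"a{i}" for i in range(np.asarray(memberships).shape[0])),
    )


class TestObjective:
    def test_zero_model_closed_form(self):
        """With w = 0, b = 0 every squared loss is (1-0)^2 = 1; placing all AD
        points at the centroids kills the distance term, so the objective is
        exactly C * (N_AD + K * N_CN)."""
        n_ad, n_cn, K, C = 6, 4, 2, 3.0
        X = np.vstack([np.zeros((n_ad, 2)), np.ones((n_cn, 2))])
        y = np.array([1] * n_ad + [-1] * n_cn)
        data = LabeledDataset(X=X, y=y, ids=tuple(map(str, range(n_ad + n_cn))))
        config = MOEConfig(K=K, C=C, t=5.0, class_weight_ratio=1.0)
        experts = [ExpertModel(w=np.zeros(2), b=0.0, d=np.zeros(2)) for _ in range(K)]
        m = np.full((n_ad, K), 1.0 / K)
        assert moe_objective(data, experts, m, config) == pytest.approx(
            C * (n_ad + K * n_cn), abs=1e-10
        )

    def test_doubling_c_doubles_zero_weight_objective(self):
        X = np.array([[0.0], [1.0]])
        data = LabeledDataset(X=X, y=np.array([1, -1]), ids=("a", "c"))
        experts = [ExpertModel(w=np.zeros(1), b=0.0, d=np.zeros(1))]
        m = np.ones((1, 1))
        v1 = moe_objective(data, experts, m, MOEConfig(K=1, C=1.0, t=2.0))
        v2 = moe_objective(data, experts, m, MOEConfig(K=1, C=2.0, t=2.0))
        assert v2 == pytest.approx(2.0 * v1, rel=1e-12)

    def test_hand_evaluated_tiny_instance(self):
        """Two AD points, one CN point, K = 2, hand-set blocks."""
        X = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]])
        y = np.array([1, 1, -1])
        data = LabeledDataset(X=X, y=y, ids=("a1", "a2", "c1"))
        C, t, rho = 2.0, 0.5, 3.0
        config = MOEConfig(K=2, C=C, t=t, class_weight_ratio=rho)
        w1, b1 = np.array([1.0, -1.0]), 0.5
        w2, b2 = np.array([0.0, 2.0]), -1.0
        d1, d2 = np.array([0.5, 0.5]), np.array([0.0, 1.0])
        m = np.array([[0.7, 0.3], [0.2, 0.8]])
        experts = [ExpertModel(w1, b1, d1), ExpertModel(w2, b2, d2)]

        expected = 0.0
        for (w, b, d, k) in ((w1, b1, d1, 0), (w2, b2, d2, 1)):
            expected += 0.5 * np.abs(w).sum()
            for i in range(2):  # AD terms
                loss = (1.0 - y[i] * (w @ X[i] + b)) ** 2
                expected += C * rho * m[i, k] * loss
                expected += t * m[i, k] ** 2 * np.sum((X[i] - d) ** 2)
            expected += C * (1.0 - y[2] * (w @ X[2] + b)) ** 2  # CN anchor
        assert moe_objective(data, experts, m, config) == pytest.approx(expected, abs=1e-10)

    def test_dimension_mismatch_raises(self, tiny_dataset):
        config = MOEConfig(K=2)
        experts = [ExpertModel(np.zeros(3), 0.0, np.zeros(3))] * 2
        with pytest.raises(ValueError, match="memberships"):
            moe_objective(tiny_dataset, experts, np.ones((5, 2)), config)


class TestInitMemberships:
    def test_k1_is_all_ones(self, tiny_dataset):
        m = init_memberships(tiny_dataset, K=1, seed=0)
        assert m.shape == (3, 1)
        assert np.all(m == 1.0)

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(1)
        X = np.vstack([
            rng.normal(0.0, 0.1, size=(15, 4)),
            rng.normal(5.0, 0.1, size=(15, 4)),
            rng.normal(-1.0, 0.3, size=(10, 4)),  # CN rows, ignored
        ])
        y = np.array([1] * 30 + [-1] * 10)
        data = LabeledDataset(X=X, y=y, ids=tuple(map(str, range(40))))
        m = init_memberships(data, K=2, seed=3)
        hard = m.argmax(axis=1)
        assert len(set(hard[:15])) == 1 and len(set(hard[15:])) == 1
        assert hard[0] != hard[15]

    def test_deterministic_given_seed(self, small_dataset):
        m1 = init_memberships(small_dataset, K=3, seed=5)
        m2 = init_memberships(small_dataset, K=3, seed=5)
        np.testing.assert_array_equal(m1, m2)

    def test_k_exceeding_ad_count_raises(self, tiny_dataset):
        with pytest.raises(ValueError, match="AD"):
            init_memberships(tiny_dataset, K=10, seed=0)


class TestUpdateExperts:
    def test_separable_limit_classifies_all_points(self):
        data = separable_dataset(n_per=20, gap=4.0, seed=2)
        m = np.ones((20, 1))
        config = MOEConfig(K=1, C=100.0, t=1.0)
        (w, b), = update_experts(data, m, config)
        pred = np.sign(data.X @ w + b)
        assert np.all(pred == data.y)

    def test_matches_convex_solver_oracle(self, tiny_dataset):
        config = MOEConfig(K=2, C=3.0, t=1.0, class_weight_ratio=2.0)
        m = np.array([[0.8, 0.2], [0.5, 0.5], [0.1, 0.9]])
        experts = update_experts(tiny_dataset, m, config)
        ad = tiny_dataset.ad_mask
        for k, (w, b) in enumerate(experts):
            sw = np.ones(5)
            sw[ad] = config.class_weight_ratio * m[:, k]
            _, _, oracle_val = weighted_l1_oracle(
                tiny_dataset.X, tiny_dataset.y.astype(float), sw, config.C
            )
            ours = expert_objective(
                tiny_dataset.X, tiny_dataset.y.astype(float), sw, config.C, w, b
            )
            assert ours <= oracle_val + 1e-4

    def test_zero_membership_raises_dead_expert(self, tiny_dataset):
        m = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(DeadExpertError, match="expert 1"):
            update_experts(tiny_dataset, m, MOEConfig(K=2))


class TestUpdateMemberships:
    def test_k1_simplex_is_trivial(self, tiny_dataset):
        experts = [ExpertModel(np.array([1.0, 0, 0]), 0.0, np.zeros(3))]
        m = update_memberships(tiny_dataset, experts, MOEConfig(K=1))
        assert np.all(m == 1.0)

    def test_symmetric_losses_and_distances_split_evenly(self):
        X = np.array([[1.0, 1.0], [0.0, 2.0]])
        y = np.array([1, -1])
        data = LabeledDataset(X=X, y=y, ids=("a", "c"))
        # mirror-image experts: equal loss and equal centroid distance
        experts = [
            ExpertModel(np.array([1.0, 0.0]), 0.0, np.array([0.0, 0.0])),
            ExpertModel(np.array([0.0, 1.0]), 0.0, np.array([2.0, 2.0])),
        ]
        m = update_memberships(data, experts, MOEConfig(K=2, C=1.0, t=1.0))
        np.testing.assert_allclose(m, [[0.5, 0.5]], atol=1e-12)

    def test_rows_match_brute_force_qp(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            K, n = 3, 20
            a = rng.uniform(0, 5, size=(n, K))
            c = rng.uniform(0.1, 4, size=(n, K))
            ours = _simplex_qp_rows(a, c)
            oracle = simplex_qp_oracle(a, c)
            assert np.max(np.abs(ours - oracle)) < 1e-6

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rows_always_on_simplex(self, seed):
        rng = np.random.default_rng(seed)
        K = rng.integers(1, 6)
        a = rng.uniform(0, 10, size=(8, K))
        c = rng.uniform(1e-6, 10, size=(8, K))
        m = _simplex_qp_rows(a, c)
        assert np.all(m >= 0)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-9)

    def test_large_t_limit_matches_plain_fcm(self, small_dataset):
        """As t >> C the update reduces to FCM memberships of the distance
        term alone: m_ik proportional to 1/D_ik for alpha = 2."""
        rng = np.random.default_rng(4)
        K = 3
        ad_X = small_dataset.X[small_dataset.ad_mask]
        # offset from the data so no distance is exactly zero
        centroids = ad_X[rng.choice(len(ad_X), K, replace=False)] + 0.05
        experts = [
            ExpertModel(rng.normal(size=small_dataset.X.shape[1]), 0.0, c)
            for c in centroids
        ]
        config = MOEConfig(K=K, C=1.0, t=1e9)
        m = update_memberships(small_dataset, experts, config)
        D = np.stack([((ad_X - c) ** 2).sum(axis=1) for c in centroids], axis=1)
        fcm = (1.0 / D) / (1.0 / D).sum(axis=1, keepdims=True)
        assert np.max(np.abs(m - fcm)) < 1e-6


class TestUpdateCentroids:
    def test_one_hot_memberships_give_group_means(self, tiny_dataset):
        m = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        d = update_centroids(tiny_dataset, m, alpha=2.0)
        ad_X = tiny_dataset.X[tiny_dataset.ad_mask]
        np.testing.assert_allclose(d[0], ad_X[:2].mean(axis=0))
        np.testing.assert_allclose(d[1], ad_X[2])

    def test_uniform_memberships_give_global_mean(self, tiny_dataset):
        m = np.full((3, 2), 0.5)
        d = update_centroids(tiny_dataset, m, alpha=2.0)
        ad_mean = tiny_dataset.X[tiny_dataset.ad_mask].mean(axis=0)
        np.testing.assert_allclose(d[0], ad_mean)
        np.testing.assert_allclose(d[1], ad_mean)

    def test_hand_computed_weighted_mean(self):
        X = np.array([[1.0], [2.0], [4.0]])
        data = LabeledDataset(X=X, y=np.array([1, 1, 1]), ids=("a", "b", "c"))
        m = np.array([[0.9], [0.1], [0.5]])
        d = update_centroids(data, m, alpha=2.0)
        expected = (0.81 * 1 + 0.01 * 2 + 0.25 * 4) / (0.81 + 0.01 + 0.25)
        assert d[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_zero_mass_raises(self, tiny_dataset):
        m = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(DeadExpertError):
            update_centroids(tiny_dataset, m, alpha=2.0)


class TestFitMoe:
    def test_objective_trace_non_increasing(self, small_dataset):
        for seed in (0, 1):
            model = fit_moe(small_dataset, MOEConfig(K=3, seed=seed, n_restarts=1))
            trace = np.array(model.objective_trace)
            assert np.all(np.diff(trace) <= 1e-8)

    def test_k1_reduces_to_single_weighted_classifier(self, small_dataset):
        config = MOEConfig(K=1, C=2.0, t=1.0, class_weight_ratio=2.0, n_restarts=1)
        model = fit_moe(small_dataset, config)
        w, b = _weighted_l1_fit(
            small_dataset.X, small_dataset.y.astype(float),
            np.where(small_dataset.ad_mask, 2.0, 1.0), config,
        )
        direct = [ExpertModel(w=w, b=b, d=model.experts[0].d)]
        m = np.ones((small_dataset.n_ad, 1))
        direct_obj = moe_objective(small_dataset, direct, m, config)
        assert model.objective_trace[-1] == pytest.approx(direct_obj, abs=1e-6)

    def test_memberships_rows_normalized(self, fitted_model):
        np.testing.assert_allclose(
            fitted_model.memberships.sum(axis=1), 1.0, atol=1e-9
        )

    def test_deterministic_given_seed(self, small_dataset):
        cfg = MOEConfig(K=2, seed=9, n_restarts=2)
        m1 = fit_moe(small_dataset, cfg)
        m2 = fit_moe(small_dataset, cfg)
        np.testing.assert_array_equal(m1.memberships, m2.memberships)
        for e1, e2 in zip(m1.experts, m2.experts):
            np.testing.assert_array_equal(e1.w, e2.w)

    def test_bpc_within_bounds(self, fitted_model):
        bpc = bezdek_pc(fitted_model.memberships)
        assert 1.0 / fitted_model.K - 1e-12 <= bpc <= 1.0 + 1e-12


class TestPredict:
    def test_centroid_point_goes_to_its_expert(self):
        experts = [
            ExpertModel(np.array([1.0, 0.0]), -5.0, np.array([0.0, 0.0])),
            ExpertModel(np.array([1.0, 0.0]), 1.0, np.array([3.0, 3.0])),
        ]
        model = make_model(experts, np.ones((1, 2)) * 0.5, MOEConfig(K=2))
        labels, idx = predict_label(model, np.array([3.0, 3.0]))
        assert idx[0] == 1
        assert labels[0] == 1  # w.x + b = 4 > 0

    def test_single_expert_reduces_to_sign(self):
        expert = ExpertModel(np.array([2.0]), -1.0, np.array([0.0]))
        model = make_model([expert], np.ones((1, 1)), MOEConfig(K=1))
        labels, _ = predict_label(model, np.array([[0.0], [1.0]]))
        np.testing.assert_array_equal(labels, [-1, 1])

    def test_zero_decision_value_maps_to_positive(self):
        expert = ExpertModel(np.array([1.0]), 0.0, np.array([0.0]))
        model = make_model([expert], np.ones((1, 1)), MOEConfig(K=1))
        labels, _ = predict_label(model, np.array([[0.0]]))
        assert labels[0] == 1

    def test_separable_holdout_is_perfect(self):
        train = separable_dataset(n_per=25, seed=3)
        test = separable_dataset(n_per=15, seed=4)
        model = fit_moe(train, MOEConfig(K=2, C=10.0, n_restarts=1, seed=0))
        pred, _ = predict_label(model, test.X)
        assert np.all(pred == test.y)


class TestCrossValidate:
    def test_separable_accuracy_is_one(self):
        data = separable_dataset(n_per=25, seed=5)
        cfg = MOEConfig(K=2, C=10.0, cv_folds=5, n_restarts=1, seed=1)
        mean, sd, accs = cross_validate(data, cfg)
        assert mean == 1.0 and sd == 0.0

    def test_deterministic_folds(self):
        data = separable_dataset(n_per=20, seed=6)
        cfg = MOEConfig(K=2, cv_folds=4, n_restarts=1, seed=2)
        r1 = cross_validate(data, cfg)
        r2 = cross_validate(data, cfg)
        np.testing.assert_array_equal(r1[2], r2[2])

    def test_folds_exceeding_class_count_raise(self, tiny_dataset):
        with pytest.raises(ValueError, match="cv_folds"):
            cross_validate(tiny_dataset, MOEConfig(K=1, cv_folds=5))


class TestValidityIndices:
    def test_bezdek_one_hot_is_one(self):
        assert bezdek_pc(np.array([[1.0, 0.0], [0.0, 1.0]])) == 1.0

    def test_bezdek_uniform_is_one_over_k(self):
        assert bezdek_pc(np.full((4, 3), 1 / 3)) == pytest.approx(1 / 3)

    def test_bezdek_hand_value(self):
        assert bezdek_pc(np.array([[0.5, 0.5], [0.8, 0.2]])) == pytest.approx(0.59)

    def test_wr_orthogonal_zero_identical_one(self):
        e1 = ExpertModel(np.array([1.0, 0.0]), 0.0, np.zeros(2))
        e2 = ExpertModel(np.array([0.0, 2.0]), 0.0, np.zeros(2))
        assert pairwise_wr([e1, e2]) == pytest.approx(0.0, abs=1e-12)
        e3 = ExpertModel(np.array([3.0, 0.0]), 0.0, np.zeros(2))
        assert pairwise_wr([e1, e3]) == pytest.approx(1.0)

    def test_wr_sixty_degrees_is_half(self):
        e1 = ExpertModel(np.array([1.0, 0.0]), 0.0, np.zeros(2))
        e2 = ExpertModel(np.array([0.5, np.sqrt(3) / 2]), 0.0, np.zeros(2))
        assert pairwise_wr([e1, e2]) == pytest.approx(0.5)

    def test_wr_single_expert_not_applicable(self):
        e = ExpertModel(np.array([1.0]), 0.0, np.zeros(1))
        assert np.isnan(pairwise_wr([e]))


class TestGridSearch:
    def test_single_point_grid_selected(self):
        data = separable_dataset(n_per=12, seed=7)
        cfg = MOEConfig(K=2, cv_folds=3, n_restarts=1, seed=0)
        rep = grid_search_select(data, cfg, C_grid=[2.0], t_grid=[1.0], rho_grid=[1.0])
        assert len(rep.table) == 1
        assert rep.selected["C"] == 2.0 and bool(rep.selected["selected"])

    def test_accuracy_ties_break_by_minimum_wr(self):
        data = separable_dataset(n_per=15, seed=8)
        cfg = MOEConfig(K=2, cv_folds=3, n_restarts=1, seed=1)
        rep = grid_search_select(
            data, cfg, C_grid=[1.0, 8.0], t_grid=[0.5], rho_grid=[1.0]
        )
        table = rep.table
        if table["acc_mean"].nunique() == 1:
            expected = table.loc[table["wr"].idxmin()]
            assert rep.selected["C"] == expected["C"]

    def test_selection_reproducible(self):
        data = separable_dataset(n_per=12, seed=9)
        cfg = MOEConfig(K=2, cv_folds=3, n_restarts=1, seed=4)
        r1 = grid_search_select(data, cfg, C_grid=[1.0, 4.0], t_grid=[1.0], rho_grid=[1.0])
        r2 = grid_search_select(data, cfg, C_grid=[1.0, 4.0], t_grid=[1.0], rho_grid=[1.0])
        assert r1.selected["C"] == r2.selected["C"]
        np.testing.assert_allclose(r1.table["acc_mean"], r2.table["acc_mean"])


def test_model_serialization_round_trip(tmp_path, fitted_model):
    path = tmp_path / "model.json"
    save_model(fitted_model, path)
    loaded = load_model(path)
    np.testing.assert_allclose(loaded.memberships, fitted_model.memberships)
    for e1, e2 in zip(loaded.experts, fitted_model.experts):
        np.testing.assert_allclose(e1.w, e2.w)
        np.testing.assert_allclose(e1.d, e2.d)
        assert e1.b == pytest.approx(e2.b)
    assert loaded.config == fitted_model.config
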