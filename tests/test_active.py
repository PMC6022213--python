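import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from preictal import (
    LabelledPool,
    Oracle,
    active_learning_round,
    e_step,
    fit_bgmm,
    init_bgmm,
    predict,
    run_learning_loop,
    select_least_confident,
    stopping_check,
    train,
)
from preictal.active import m_step

from _oracles import naive_e_step, naive_weighted_moments
from _simulate import make_history_pool, simulate_bgmm_pool


class TestInit:
    def test_moment_initialization_from_labelled_samples(self):
        rng = np.random.default_rng(0)
        m = 2.0
        X = np.vstack([rng.normal(-m, 0.5, (10, 3)), rng.normal(m, 0.5, (10, 3))])
        y = np.array([0] * 10 + [1] * 10)
        pool = LabelledPool.create(X, y, K=2)
        state = init_bgmm(pool, seed=0)
        assert np.allclose(state.mu[0], -m, atol=0.6)
        assert np.allclose(state.mu[1], m, atol=0.6)
        assert np.allclose(state.alpha, [0.5, 0.5])

    def test_initialization_is_deterministic(self):
        pool, _ = make_history_pool(seed=1)
        a, b = init_bgmm(pool, seed=4), init_bgmm(pool, seed=4)
        assert np.array_equal(a.mu, b.mu) and np.array_equal(a.pi, b.pi)

    def test_unlabelled_pool_rejected(self):
        pool = LabelledPool.create(np.zeros((5, 2)), np.full(5, -1))
        with pytest.raises(ValueError):
            init_bgmm(pool)


class TestEStep:
    def test_labelled_samples_get_indicator_responsibilities(self):
        pool, _ = make_history_pool(seed=2)
        state = init_bgmm(pool, seed=0)
        resp = e_step(state, pool)
        lab = pool.labelled
        assert np.array_equal(resp[lab, pool.y[lab]], np.ones(lab.size))
        assert np.allclose(resp.sum(axis=1), 1.0)

    def test_symmetric_midpoint_is_maximally_ambiguous(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(2.0, 1.0, (20, 2))
        X = np.vstack([-pts, pts, np.zeros((1, 2))])  # mirror classes + midpoint
        y = np.array([0] * 20 + [1] * 20 + [-1])
        pool = LabelledPool.create(X, y, K=1)
        state = init_bgmm(pool, seed=0)
        resp = e_step(state, pool)
        assert resp[-1] == pytest.approx([0.5, 0.5], abs=1e-9)

    @pytest.mark.parametrize("use_soft", [True, False])
    def test_matches_naive_term_by_term_oracle(self, use_soft):
        pool, _ = make_history_pool(seed=3, n=40)
        state = init_bgmm(pool, seed=1, use_soft=use_soft)
        resp = e_step(state, pool)
        expected = naive_e_step(state, pool)
        np.testing.assert_allclose(resp, expected, rtol=1e-8, atol=1e-12)


class TestMStep:
    def test_fully_labelled_reduces_to_supervised_moments(self):
        pool, y = make_history_pool(seed=4, labelled_frac=1.1)
        state = init_bgmm(pool, seed=0)
        resp = np.zeros((pool.N, 2))
        resp[np.arange(pool.N), y] = 1.0
        new = m_step(state, pool, resp)
        for c in (0, 1):
            np.testing.assert_allclose(new.mu[c], pool.X[y == c].mean(axis=0))

    def test_uniform_responsibilities_collapse_to_global_mean(self):
        pool, _ = make_history_pool(seed=5)
        state = init_bgmm(pool, seed=0)
        new = m_step(state, pool, np.full((pool.N, 2), 0.5))
        np.testing.assert_allclose(new.mu[0], pool.X.mean(axis=0))
        np.testing.assert_allclose(new.mu[0], new.mu[1])
        assert np.allclose(new.alpha, [0.5, 0.5])

    def test_matches_naive_weighted_moment_oracle(self):
        pool, _ = make_history_pool(seed=6, n=30)
        state = init_bgmm(pool, seed=0)
        rng = np.random.default_rng(7)
        resp = rng.random((pool.N, 1))
        resp = np.hstack([resp, 1.0 - resp])
        new = m_step(state, pool, resp)
        alpha, mu, var, pi = naive_weighted_moments(resp, pool)
        np.testing.assert_allclose(new.alpha, alpha, rtol=1e-10)
        np.testing.assert_allclose(new.mu, mu, rtol=1e-10)
        np.testing.assert_allclose(new.var, np.maximum(var, new.var_floor), rtol=1e-8)
        np.testing.assert_allclose(new.pi, pi, rtol=1e-10)

    def test_class_collapse_raises(self):
        pool, _ = make_history_pool(seed=8)
        state = init_bgmm(pool, seed=0)
        resp = np.zeros((pool.N, 2))
        resp[:, 0] = 1.0
        from preictal.active import ClassCollapseError

        with pytest.raises(ClassCollapseError):
            m_step(state, pool, resp)


class TestFit:
    def test_loglik_trace_monotone(self):
        pool, _ = make_history_pool(seed=9, n=60, labelled_frac=0.2)
        state = fit_bgmm(pool, seed=0)
        trace = np.array(state.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_fully_labelled_pool_converges_immediately(self):
        pool, _ = make_history_pool(seed=10, labelled_frac=1.1)
        state = fit_bgmm(pool, seed=0)
        assert state.converged and len(state.loglik_trace) <= 2

    def test_parameter_recovery_from_model_draws(self):
        pool, true_mu, true_alpha = simulate_bgmm_pool(seed=0, n=1000)
        state = fit_bgmm(pool, seed=0, cov_type="full")
        assert state.converged
        for c in (0, 1):
            assert np.linalg.norm(state.mu[c] - true_mu[c]) < 0.3
        assert np.abs(state.alpha - true_alpha).max() < 0.1


class TestSelection:
    def test_most_ambiguous_sample_selected(self):
        pool, _ = make_history_pool(seed=11, n=3, labelled_frac=0.9)
        state = init_bgmm(pool, seed=0)
        state.resp = np.array([[0.5, 0.5], [0.9, 0.1], [0.99, 0.01]])
        assert select_least_confident(state, np.arange(3), 1).tolist() == [0]

    def test_batch_larger_than_candidates_returns_all_sorted(self):
        pool, _ = make_history_pool(seed=12, n=3, labelled_frac=0.9)
        state = init_bgmm(pool, seed=0)
        state.resp = np.array([[0.9, 0.1], [0.5, 0.5], [0.7, 0.3]])
        assert select_least_confident(state, np.arange(3), 10).tolist() == [1, 2, 0]

    def test_selection_matches_independent_ranking(self):
        pool, _ = make_history_pool(seed=13, n=100, labelled_frac=0.3)
        state = fit_bgmm(pool, seed=0)
        cand = pool.unlabelled
        got = select_least_confident(state, cand, 5)
        score = {j: 1.0 - state.resp[j].max() for j in cand}
        expected = sorted(sorted(cand), key=lambda j: -score[j])[:5]
        assert got.tolist() == expected

    def test_empty_candidates_give_empty_selection(self):
        pool, _ = make_history_pool(seed=14)
        state = init_bgmm(pool, seed=0)
        assert select_least_confident(state, np.array([]), 3).size == 0

    def test_tie_break_is_lowest_index(self):
        pool, _ = make_history_pool(seed=15, n=4, labelled_frac=0.9)
        state = init_bgmm(pool, seed=0)
        state.resp = np.array([[0.7, 0.3]] * 4)
        assert select_least_confident(state, np.arange(4), 2).tolist() == [0, 1]


class TestStopping:
    def test_flat_history_stops(self):
        assert stopping_check([0.6, 0.7, 0.7, 0.7], window=2, tol=1e-3)

    def test_increasing_history_continues(self):
        assert not stopping_check([0.5, 0.6, 0.7, 0.8], window=2, tol=1e-3)

    def test_short_history_continues(self):
        assert not stopping_check([0.7, 0.7], window=2, tol=1e-3)

    @given(
        st.lists(st.floats(min_value=0.5, max_value=1.0), min_size=3, max_size=8),
        st.floats(min_value=1e-4, max_value=0.1),
    )
    @settings(max_examples=50, derandomize=True)
    def test_definition_holds_for_arbitrary_histories(self, history, tol):
        expected = all(
            abs(history[i + 1] - history[i]) < tol
            for i in range(len(history) - 3, len(history) - 1)
        )
        assert stopping_check(history, window=2, tol=tol) == expected


class TestRounds:
    def test_budget_zero_round_is_a_no_op(self):
        pool, y = make_history_pool(seed=16)
        lab = pool.labelled
        model = train(pool.X[lab], pool.y[lab], seed=0)
        oracle = Oracle(labels=y, budget=0)
        before = pool.y.copy()
        pool2, model2, stop = active_learning_round(pool, model, oracle, seed=0)
        assert stop and np.array_equal(pool2.y, before) and model2 is model

    def test_labelled_count_grows_by_batch_each_round(self):
        pool, y = make_history_pool(seed=17, n=100, labelled_frac=0.1)
        lab = pool.labelled
        model = train(pool.X[lab], pool.y[lab], seed=0)
        oracle = Oracle(labels=y, budget=100)
        start = pool.labelled.size
        for _ in range(5):
            pool, model, _ = active_learning_round(pool, model, oracle, batch_size=5, seed=0)
        assert pool.labelled.size == start + 25
        assert len(oracle.log) == 25

    def test_oracle_budget_is_respected(self):
        pool, y = make_history_pool(seed=18, n=60, labelled_frac=0.1)
        oracle = Oracle(labels=y, budget=7)
        model, final = run_learning_loop(
            pool.X, pool.y, oracle, method="bgmm", batch_size=3, seed=0
        )
        assert len(oracle.log) <= 7

    @pytest.mark.parametrize("method", ["bgmm", "uncertainty", "random"])
    def test_learning_does_not_hurt_on_separable_data(self, method):
        pool, y = make_history_pool(seed=19, n=120, labelled_frac=0.08, sep=2.5)
        init = pool.y.copy()
        lab = np.flatnonzero(init >= 0)
        before = predict(train(pool.X[lab], init[lab], seed=0), pool.X)
        err_before = np.mean(before.crisp != y)
        oracle = Oracle(labels=y, budget=30)
        model, _ = run_learning_loop(
            pool.X, init, oracle, method=method, batch_size=5, seed=0
        )
        err_after = np.mean(predict(model, pool.X).crisp != y)
        assert err_after <= err_before + 1e-9
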