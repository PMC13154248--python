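import numpy as np
import pytest

from mvgsc import build_similarity_set, build_views, run_attribute_stage
from mvgsc.attribute import (
    attribute_objective,
    init_attribute,
    solve_embedding,
    update_unified,
    update_view_graphs,
    update_weights,
)
from mvgsc.data_io import ValidationError
from mvgsc.structure import count_components
from tests.conftest import union_find_components


def _simset(rng, n=16, k=5):
    X = rng.random((n, 8)) * 2
    return build_similarity_set(build_views(X), k=k)


class TestInit:
    def test_identical_graphs_average_is_graph(self, rng):
        S = _simset(rng)
        S.graphs = [S.graphs[0].copy() for _ in range(3)]
        state = init_attribute(S, 2)
        np.testing.assert_allclose(state.U, S.graphs[0], atol=1e-12)

    def test_weights_uniform_sum_one(self, rng):
        state = init_attribute(_simset(rng), 3)
        np.testing.assert_allclose(state.w, 1.0 / 3.0)

    def test_embedding_orthonormal(self, rng):
        state = init_attribute(_simset(rng), 3)
        np.testing.assert_allclose(state.F1.T @ state.F1, np.eye(3), atol=1e-8)

    def test_too_many_clusters(self, rng):
        with pytest.raises(ValidationError):
            init_attribute(_simset(rng, n=10, k=3), 11)


class TestSolveEmbedding:
    def test_two_blocks_two_zero_eigenvalues(self, two_block_graph):
        _, vals = solve_embedding(two_block_graph, 2)
        assert np.all(np.abs(vals) <= 1e-8)

    def test_trace_equals_sum_of_smallest_eigenvalues(self, rng):
        U = rng.random((12, 12))
        F, _ = solve_embedding(U, 4)
        W = (U + U.T) / 2
        L = np.diag(W.sum(axis=1)) - W
        all_vals = np.linalg.eigvalsh(L)  # independent full eigendecomposition
        assert np.trace(F.T @ L @ F) == pytest.approx(np.sum(all_vals[:4]), abs=1e-8)


class TestViewGraphUpdate:
    def test_zero_weight_recovers_initial_row(self, rng):
        """With w_v = 0 the row subproblem is exactly the adaptive-KNN init."""
        S = _simset(rng)
        init_rows = [G.copy() for G in S.graphs]
        state = init_attribute(S, 2)
        state.w_raw = np.zeros(3)
        update_view_graphs(state)
        for G, G0 in zip(state.S.graphs, init_rows):
            np.testing.assert_allclose(G, G0, atol=1e-8)

    def test_huge_weight_pulls_toward_consensus(self, rng):
        S = _simset(rng)
        state = init_attribute(S, 2)
        state.w_raw = np.full(3, 1e12)
        update_view_graphs(state)
        # each row -> simplex projection of u_i restricted to the view support
        from mvgsc._simplex import project_simplex

        for v in range(3):
            sup = S.supports[v][0]
            expected = project_simplex(state.U[0, sup])
            np.testing.assert_allclose(state.S.graphs[v][0, sup], expected, atol=1e-6)

    def test_row_update_beats_random_search(self, rng):
        """Closed-form row solution vs 1000 random simplex points (8 cells)."""
        S = _simset(rng, n=8, k=4)
        state = init_attribute(S, 2)
        update_weights(state)
        update_view_graphs(state)
        for v in range(3):
            d2, sup, alpha = S.distances[v], S.supports[v], S.alphas[v]
            wv = state.w_raw[v]
            for i in range(8):
                s_opt = state.S.graphs[v][i, sup[i]]

                def obj(s):
                    return (
                        d2[i, sup[i]] @ s
                        + alpha[i] * s @ s
                        + wv * np.sum((s - state.U[i, sup[i]]) ** 2)
                    )

                rand = rng.dirichlet(np.ones(len(sup[i])), size=1000)
                assert obj(s_opt) <= np.min([obj(r) for r in rand]) + 1e-9


class TestWeightUpdate:
    def test_ratio_rule(self, rng):
        S = _simset(rng)
        state = init_attribute(S, 2)
        # craft views so ||U - S^1|| = 2 ||U - S^2||
        U = state.U
        E = np.zeros_like(U)
        E[0, 1] = 1.0
        state.S.graphs = [U + 2 * E, U + E, U + E]
        update_weights(state)
        assert state.w_raw[1] == pytest.approx(2 * state.w_raw[0])

    def test_equal_views_uniform(self, rng):
        S = _simset(rng)
        state = init_attribute(S, 2)
        state.S.graphs = [state.U.copy() + 0.01 for _ in range(3)]
        update_weights(state)
        np.testing.assert_allclose(state.w, 1.0 / 3.0)

    def test_matching_view_dominates(self, rng):
        S = _simset(rng)
        state = init_attribute(S, 2)
        state.S.graphs[0] = state.U.copy()  # exact match -> floored norm, huge weight
        update_weights(state)
        assert state.w[0] > 0.99


class TestUnifiedUpdate:
    def test_lambda_zero_single_view_returns_view(self, rng):
        X = rng.random((12, 6))
        from mvgsc.views import ViewSet, gaussian_kernel

        K = gaussian_kernel(X, 10.0)
        vs = ViewSet([K], ["gauss"])
        S = build_similarity_set(vs, k=4)
        state = init_attribute(S, 2)
        state.lambda_rank = 0.0
        update_unified(state)
        np.testing.assert_allclose(state.U, S.graphs[0], atol=1e-10)

    def test_lambda_zero_equal_weights_gives_mean(self, rng):
        S = _simset(rng)
        state = init_attribute(S, 2)
        state.lambda_rank = 0.0
        state.w_raw = np.full(3, 1.0 / 3.0)
        update_unified(state)
        mean = sum(S.graphs) / 3.0
        np.testing.assert_allclose(state.U, mean, atol=1e-10)

    def test_row_update_beats_random_search(self, rng):
        S = _simset(rng, n=8, k=4)
        state = init_attribute(S, 2)
        update_weights(state)
        lam = state.lambda_rank
        F = state.F1
        P = np.sum((F[:, None, :] - F[None, :, :]) ** 2, axis=-1)
        update_unified(state)
        for i in range(8):
            idx = np.flatnonzero(state.U_support[i])
            u_opt = state.U[i, idx]

            def obj(u):
                val = lam * P[i, idx] @ u
                for wv, Sv in zip(state.w_raw, S.graphs):
                    val += wv * np.sum((u - Sv[i, idx]) ** 2)
                return val

            rand = rng.dirichlet(np.ones(len(idx)), size=1000)
            assert obj(u_opt) <= np.min([obj(r) for r in rand]) + 1e-9


class TestRunAttributeStage:
    def test_separated_blocks_reach_c_components(self, small_dataset):
        em, _ = small_dataset
        S = build_similarity_set(build_views(em), k=8)
        state = run_attribute_stage(S, 3)
        assert count_components(state.U) == 3
        assert union_find_components(state.U) == 3

    def test_objective_monotone_at_fixed_lambda(self, rng):
        S = _simset(rng, n=20, k=6)
        state = run_attribute_stage(S, 3, max_iter=15)
        tr = state.objective_trace
        lam = state.lambda_trace
        for a, b, la, lb in zip(tr, tr[1:], lam, lam[1:]):
            if la == lb:
                assert b <= a + 1e-9 * max(abs(a), 1.0)

    def test_rows_stay_on_simplex(self, rng):
        S = _simset(rng, n=15, k=5)
        state = run_attribute_stage(S, 3, max_iter=8)
        np.testing.assert_allclose(state.U.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(state.U >= -1e-12) and np.all(np.diag(state.U) == 0)
        for G in state.S.graphs:
            np.testing.assert_allclose(G.sum(axis=1), 1.0, atol=1e-8)

    def test_single_view_degenerate_runs(self, rng):
        X = rng.random((12, 5))
        from mvgsc.views import ViewSet, gaussian_kernel

        vs = ViewSet([gaussian_kernel(X, 10.0)], ["gauss"])
        S = build_similarity_set(vs, k=4)
        state = run_attribute_stage(S, 2, max_iter=5)
        assert state.U.shape == (12, 12)
        np.testing.assert_allclose(state.U.sum(axis=1), 1.0, atol=1e-8)

    def test_permutation_equivariance(self, rng):
        X = rng.random((14, 6)) * 2
        perm = rng.permutation(14)
        s1 = run_attribute_stage(build_similarity_set(build_views(X), k=4), 2, max_iter=5)
        s2 = run_attribute_stage(
            build_similarity_set(build_views(X[perm]), k=4), 2, max_iter=5
        )
        np.testing.assert_allclose(s2.U, s1.U[np.ix_(perm, perm)], atol=1e-6)
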