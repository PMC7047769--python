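"""Optimizer blocks against brute-force oracles, plus whole-fit properties."""

import numpy as np
import pytest

from mvclda.exceptions import NumericalError
from mvclda.optimizer import (
    ConsensusState,
    HyperParams,
    build_laplacian,
    fit,
    objective_value,
    simplex_project,
    simplex_project_rows,
    solve_label_matrix,
    update_consensus_graph,
    update_view_weights,
)
from mvclda.similarity import SimilarityView, ViewSet, build_views

from conftest import oracle_simplex_project, random_similarity


def make_viewset(rng, p, q, n=3, m=3):
    dv = tuple(
        SimilarityView(random_similarity(rng, q), "disease", f"v{k}") for k in range(n)
    )
    lv = tuple(
        SimilarityView(random_similarity(rng, p), "lncrna", f"u{k}") for k in range(m)
    )
    return ViewSet(dv, lv)


class TestLaplacian:
    def test_identity_graph_has_zero_laplacian(self):
        assert np.allclose(build_laplacian(np.eye(4)), 0.0)

    def test_all_ones_two_by_two(self):
        expected = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert np.allclose(build_laplacian(np.ones((2, 2))), expected)

    def test_random_graph_laplacian_is_psd_with_zero_row_sums(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            L = build_laplacian(rng.random((6, 6)))
            assert np.allclose(L, L.T)
            assert np.allclose(L.sum(axis=1), 0.0, atol=1e-12)
            assert np.linalg.eigvalsh(L).min() > -1e-10

    def test_rejects_nonsquare(self):
        with pytest.raises(ValueError):
            build_laplacian(np.ones((2, 3)))


class TestSimplexProjection:
    def test_feasible_point_unchanged(self):
        v = np.array([0.2, 0.3, 0.5])
        assert np.allclose(simplex_project(v), v)

    def test_symmetric_point_projects_to_uniform(self):
        assert np.allclose(simplex_project(np.array([0.5, 0.5, 0.5])), 1.0 / 3.0)

    def test_vertex_case(self):
        assert np.allclose(simplex_project(np.array([2.0, 0.0, 0.0])), [1.0, 0.0, 0.0])

    def test_matches_qp_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            v = rng.normal(scale=2.0, size=5)
            ours = simplex_project(v)
            assert ours.min() >= 0 and abs(ours.sum() - 1) < 1e-12
            assert np.abs(ours - oracle_simplex_project(v)).max() < 1e-6

    def test_rows_variant_matches_vector_variant(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(10, 7))
        rows = simplex_project_rows(M)
        for i in range(10):
            assert np.allclose(rows[i], simplex_project(M[i]))

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            simplex_project(np.array([]))


class TestConsensusGraphUpdate:
    def test_zero_smoothness_returns_stochastic_view(self):
        rng = np.random.default_rng(2)
        S = rng.random((5, 5))
        S /= S.sum(axis=1, keepdims=True)
        out = update_consensus_graph([S], np.ones(1), rng.random((4, 5)), 0.0, "disease")
        assert np.allclose(out, S, atol=1e-12)

    def test_zero_smoothness_projects_weighted_average(self):
        rng = np.random.default_rng(3)
        views = [random_similarity(rng, 6) for _ in range(3)]
        w = np.array([0.2, 0.5, 0.3])
        out = update_consensus_graph(views, w, rng.random((6, 4)), 0.0, "lncrna")
        base = sum(wi * A for wi, A in zip(w, views))
        for i in range(6):
            assert np.allclose(out[i], simplex_project(base[i]))

    def test_matches_per_row_qp_oracle(self):
        # each row solves min ||s - (sum_v w_v A_v)_i + (alpha/2) h_i||^2 on the simplex
        rng = np.random.default_rng(4)
        views = [random_similarity(rng, 3) for _ in range(2)]
        w = np.array([0.6, 0.4])
        F = rng.random((4, 3))
        alpha = 0.7
        out = update_consensus_graph(views, w, F, alpha, "disease")
        base = sum(wi * A for wi, A in zip(w, views))
        cols = F.T
        for i in range(3):
            h = np.array([np.sum((cols[i] - cols[j]) ** 2) for j in range(3)])
            target = base[i] - (alpha / 2.0) * h
            assert np.abs(out[i] - oracle_simplex_project(target)).max() < 1e-6

    def test_row_and_column_orientation_differ(self):
        rng = np.random.default_rng(5)
        view = [random_similarity(rng, 4)]
        F = rng.random((4, 4))
        disease = update_consensus_graph(view, np.ones(1), F, 0.5, "disease")
        lncrna = update_consensus_graph(view, np.ones(1), F, 0.5, "lncrna")
        assert not np.allclose(disease, lncrna)


class TestViewWeights:
    def test_single_view_gets_all_weight(self):
        rng = np.random.default_rng(6)
        S = rng.random((4, 4))
        assert np.allclose(update_view_weights(S, [random_similarity(rng, 4)]), [1.0])

    def test_exact_view_match_is_recovered(self):
        rng = np.random.default_rng(7)
        views = [random_similarity(rng, 8) for _ in range(3)]
        w = update_view_weights(views[1], views)
        assert w[1] > 1 - 1e-4
        assert abs(w.sum() - 1) < 1e-10 and w.min() >= 0

    def test_identical_views_share_weight_uniformly(self):
        rng = np.random.default_rng(8)
        A = random_similarity(rng, 5)
        S = rng.random((5, 5))
        w = update_view_weights(S, [A, A, A])
        assert np.allclose(w, 1.0 / 3.0, atol=1e-10)


class TestSylvesterSolve:
    def test_zero_coupling_returns_y(self):
        rng = np.random.default_rng(9)
        Y = rng.random((6, 5))
        L1 = build_laplacian(rng.random((6, 6)))
        L2 = build_laplacian(rng.random((5, 5)))
        F = solve_label_matrix(L1, L2, Y, alpha=0.0, beta=0.0)
        assert np.abs(F - Y).max() < 1e-12

    def test_scalar_problem(self):
        F = solve_label_matrix(np.zeros((1, 1)), np.zeros((1, 1)), np.array([[0.7]]), 0.3, 0.4)
        assert F[0, 0] == pytest.approx(0.7)

    def test_residual_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            Y = rng.random((6, 5))
            L1 = build_laplacian(rng.random((6, 6)))
            L2 = build_laplacian(rng.random((5, 5)))
            F = solve_label_matrix(L1, L2, Y, 0.1, 0.1)
            residual = (0.2 * L1 + np.eye(6)) @ F + 0.2 * F @ L2 - Y
            assert np.linalg.norm(residual) / np.linalg.norm(Y) < 1e-8

    def test_rejects_asymmetric_laplacian(self):
        bad = np.array([[1.0, 2.0], [0.0, 1.0]])
        with pytest.raises(NumericalError):
            solve_label_matrix(bad, np.zeros((2, 2)), np.ones((2, 2)), 0.1, 0.1)


class TestObjective:
    def test_vanishes_at_exact_fit_with_zero_coupling(self):
        rng = np.random.default_rng(11)
        views = make_viewset(rng, 4, 3)
        Y = rng.random((4, 3))
        wD = np.array([0.5, 0.2, 0.3])
        wL = np.array([0.1, 0.6, 0.3])
        SD = sum(w * v.values for w, v in zip(wD, views.disease_views))
        SL = sum(w * v.values for w, v in zip(wL, views.lncrna_views))
        state = ConsensusState(SD=SD, SL=SL, wD=wD, wL=wL, F=Y.copy())
        params = HyperParams(alpha=0.0, beta=0.0)
        assert objective_value(state, views, Y, params) == pytest.approx(0.0, abs=1e-20)

    def test_trace_term_equals_pairwise_distance_form(self):
        # 2a Tr(F L_SD F^T) must equal a * sum_ij SD_ij ||F_:,i - F_:,j||^2
        rng = np.random.default_rng(12)
        F = rng.random((5, 4))
        SD = rng.random((4, 4))
        lhs = 2.0 * np.trace(F @ build_laplacian(SD) @ F.T)
        cols = F.T
        rhs = sum(
            SD[i, j] * np.sum((cols[i] - cols[j]) ** 2)
            for i in range(4)
            for j in range(4)
        )
        assert lhs == pytest.approx(rhs)

    def test_nonnegative_on_random_states(self):
        rng = np.random.default_rng(13)
        views = make_viewset(rng, 5, 4)
        Y = rng.random((5, 4))
        state = ConsensusState(
            SD=rng.random((4, 4)), SL=rng.random((5, 5)),
            wD=np.full(3, 1 / 3), wL=np.full(3, 1 / 3), F=rng.random((5, 4)),
        )
        assert objective_value(state, views, Y, HyperParams(alpha=0.3, beta=0.2)) >= 0


class TestFit:
    def test_zero_coupling_decouples_blocks(self):
        rng = np.random.default_rng(14)
        views = make_viewset(rng, 6, 5)
        Y = (rng.random((6, 5)) < 0.4).astype(float)
        state = fit(Y, views, HyperParams(alpha=0.0, beta=0.0))
        assert np.abs(state.F - Y).max() < 1e-10
        base = sum(w * v.values for w, v in zip(state.wD, views.disease_views))
        assert np.allclose(state.SD, simplex_project_rows(base), atol=1e-10)

    def test_objective_trace_monotone_on_random_instances(self):
        rng = np.random.default_rng(15)
        for _ in range(5):
            views = make_viewset(rng, 20, 15)
            Y = (rng.random((20, 15)) < 0.2).astype(float)
            state = fit(Y, views, HyperParams(alpha=0.05, beta=0.05))
            trace = np.array(state.objective_trace)
            assert np.all(trace[1:] <= trace[:-1] * (1 + 1e-8))
            state.validate()

    def test_small_alpha_beta_limit_recovers_y(self):
        rng = np.random.default_rng(16)
        views = make_viewset(rng, 8, 6)
        Y = (rng.random((8, 6)) < 0.3).astype(float)
        state = fit(Y, views, HyperParams(alpha=1e-12, beta=1e-12))
        assert np.linalg.norm(state.F - Y) < 1e-9

    def test_permutation_equivariance_of_predictions(self, small_data):
        assoc, ontology, _ = small_data
        views = build_views(assoc, ontology)
        params = HyperParams()
        state = fit(assoc, views, params)

        rng = np.random.default_rng(17)
        perm = rng.permutation(assoc.n_lncrnas)
        permuted_assoc = assoc.with_values(assoc.values[perm])
        permuted_views = ViewSet(
            views.disease_views,
            tuple(
                SimilarityView(v.values[np.ix_(perm, perm)], "lncrna", v.name)
                for v in views.lncrna_views
            ),
        )
        permuted_state = fit(permuted_assoc, permuted_views, params)
        assert np.allclose(permuted_state.F, state.F[perm], atol=1e-8)

    def test_noise_views_lose_weight_to_informative_view(self, small_data):
        assoc, ontology, _ = small_data
        views = build_views(assoc, ontology)
        semantic = views.disease_views[0]
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            noisy = ViewSet(
                (
                    semantic,
                    SimilarityView(random_similarity(rng, semantic.n), "disease", "noise1"),
                    SimilarityView(random_similarity(rng, semantic.n), "disease", "noise2"),
                ),
                views.lncrna_views,
            )
            state = fit(assoc, noisy, HyperParams())
            wins += int(np.argmax(state.wD) == 0)
        assert wins >= 3
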