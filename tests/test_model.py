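import numpy as np
import pytest

from lpnmf.model import (
    Hyperparams,
    ProjectedGraphNMF,
    build_importance,
    complete_latent,
    laplacian,
    objective,
    update_factors,
    update_view_weights,
)


class TestImportance:
    def test_delta_one_is_all_ones(self):
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_array_equal(build_importance(A, 1.0), np.ones((2, 2)))

    def test_direct_rule(self):
        np.testing.assert_array_equal(
            build_importance(np.array([[1.0, 0.0]]), 2.0), [[2.0, 1.0]]
        )

    def test_all_zero_interactions(self):
        np.testing.assert_array_equal(
            build_importance(np.zeros((3, 2)), 5.0), np.ones((3, 2))
        )

    def test_delta_below_one_rejected(self):
        with pytest.raises(ValueError):
            build_importance(np.zeros((2, 2)), 0.5)


class TestLaplacian:
    def test_all_ones_two_by_two(self):
        D, L = laplacian(np.ones((2, 2)))
        np.testing.assert_array_equal(D, np.diag([2.0, 2.0]))
        np.testing.assert_array_equal(L, [[1.0, -1.0], [-1.0, 1.0]])

    def test_zero_matrix(self):
        D, L = laplacian(np.zeros((3, 3)))
        assert D.sum() == 0 and L.sum() == 0

    def test_rows_sum_to_zero(self, rng):
        M = rng.random((6, 6))
        S = 0.5 * (M + M.T)
        _, L = laplacian(S)
        np.testing.assert_allclose(L.sum(axis=1), 0.0, atol=1e-12)

    def test_quadratic_form_identity(self, rng):
        M = rng.random((5, 5))
        S = 0.5 * (M + M.T)
        _, L = laplacian(S)
        x = rng.normal(size=5)
        direct = 0.5 * sum(
            S[i, j] * (x[i] - x[j]) ** 2 for i in range(5) for j in range(5)
        )
        assert x @ L @ x == pytest.approx(direct, abs=1e-10)

    def test_asymmetric_rejected(self, rng):
        with pytest.raises(ValueError):
            laplacian(rng.random((4, 4)))


def _random_instance(rng, n_l=5, n_p=3, d=2, n_lv=2, n_pv=1):
    U = rng.random((n_l, d))
    V = rng.random((n_p, d))
    lnc_views = [rng.random((n_l, 4)) for _ in range(n_lv)]
    prot_views = [rng.random((n_p, 3)) for _ in range(n_pv)]
    PLs = [rng.random((d, 4)) for _ in range(n_lv)]
    PPs = [rng.random((d, 3)) for _ in range(n_pv)]
    alpha = update_view_weights(np.arange(1, n_lv + 1, dtype=float), 5.0)
    beta = update_view_weights(np.arange(1, n_pv + 1, dtype=float), 5.0)
    A_bar = rng.random((n_l, n_p))
    A = (A_bar > 0.6).astype(float)
    C = build_importance(A, 2.0)
    SM = rng.random((n_l, n_l))
    SL = 0.5 * (SM + SM.T)
    SM = rng.random((n_p, n_p))
    SP = 0.5 * (SM + SM.T)
    D_l, L_l = laplacian(SL)
    D_p, L_p = laplacian(SP)
    return dict(
        U=U, V=V, PLs=PLs, PPs=PPs, alpha=alpha, beta=beta, A_bar=A_bar, C=C,
        lnc_views=lnc_views, prot_views=prot_views, SL=SL, SP=SP,
        D_l=D_l, L_l=L_l, D_p=D_p, L_p=L_p,
    )


def _objective_oracle(inst, hp):
    """Term-by-term independent evaluation of the training objective."""
    U, V = inst["U"], inst["V"]
    J = 0.5 * np.linalg.norm(inst["C"] * (inst["A_bar"] - U @ V.T), "fro") ** 2
    for a, F, P in zip(inst["alpha"], inst["lnc_views"], inst["PLs"]):
        J += 0.5 * a**hp.eta * np.linalg.norm(F @ P.T - U, "fro") ** 2
    for b, F, P in zip(inst["beta"], inst["prot_views"], inst["PPs"]):
        J += 0.5 * b**hp.eta * np.linalg.norm(F @ P.T - V, "fro") ** 2
    J += 0.5 * hp.lam * (np.trace(U.T @ inst["L_l"] @ U) + np.trace(V.T @ inst["L_p"] @ V))
    for P in inst["PLs"] + inst["PPs"]:
        J += 0.5 * hp.mu * sum(np.sum(np.abs(P[k])) ** 2 for k in range(P.shape[0]))
    J += 0.5 * hp.gamma * (np.linalg.norm(U, "fro") ** 2 + np.linalg.norm(V, "fro") ** 2)
    return J


class TestObjective:
    def test_zero_model_zero_data_is_zero(self):
        hp = Hyperparams()
        J = objective(
            np.zeros((2, 2)), np.zeros((3, 2)), [], [], np.zeros(0), np.zeros(0),
            np.zeros((2, 3)), np.ones((2, 3)), [], [], np.zeros((2, 2)),
            np.zeros((3, 3)), hp,
        )
        assert J == 0.0

    def test_perfect_factorization_unregularized(self, rng):
        hp = Hyperparams(lam=0.0, mu=0.0, gamma=0.0)
        U = rng.random((4, 2))
        V = rng.random((3, 2))
        J = objective(
            U, V, [], [], np.zeros(0), np.zeros(0), U @ V.T, np.ones((4, 3)),
            [], [], np.zeros((4, 4)), np.zeros((3, 3)), hp,
        )
        assert J == pytest.approx(0.0, abs=1e-20)

    def test_matches_independent_term_by_term_oracle(self, rng):
        hp = Hyperparams()
        inst = _random_instance(rng)
        J = objective(
            inst["U"], inst["V"], inst["PLs"], inst["PPs"], inst["alpha"],
            inst["beta"], inst["A_bar"], inst["C"], inst["lnc_views"],
            inst["prot_views"], inst["L_l"], inst["L_p"], hp,
        )
        assert J == pytest.approx(_objective_oracle(inst, hp), rel=1e-12)


def _sweep(inst, hp):
    return update_factors(
        inst["U"], inst["V"], inst["PLs"], inst["PPs"], inst["alpha"],
        inst["beta"], inst["A_bar"], inst["C"], inst["lnc_views"],
        inst["prot_views"], inst["SL"], inst["SP"], inst["D_l"], inst["D_p"], hp,
    )


class TestUpdateFactors:
    def test_zero_entries_stay_zero(self, rng):
        hp = Hyperparams()
        inst = _random_instance(rng)
        inst["U"][0, 0] = 0.0
        U, _, _, _ = _sweep(inst, hp)
        assert U[0, 0] == 0.0

    def test_exact_factorization_is_fixed_point(self, rng):
        # with lam=mu=gamma=0, C=1 and no views, an exact nonneg
        # factorization satisfies numerator == denominator elementwise
        hp = Hyperparams(lam=0.0, mu=0.0, gamma=0.0, delta=1.0)
        U = rng.random((5, 2)) + 0.1
        V = rng.random((4, 2)) + 0.1
        inst = dict(
            U=U.copy(), V=V.copy(), PLs=[], PPs=[], alpha=np.zeros(0),
            beta=np.zeros(0), A_bar=U @ V.T, C=np.ones((5, 4)),
            lnc_views=[], prot_views=[], SL=np.zeros((5, 5)), SP=np.zeros((4, 4)),
            D_l=np.zeros((5, 5)), D_p=np.zeros((4, 4)),
        )
        U2, V2, _, _ = _sweep(inst, hp)
        np.testing.assert_allclose(U2, U, atol=1e-12)
        np.testing.assert_allclose(V2, V, atol=1e-12)

    def test_reduces_to_textbook_nmf(self, rng):
        """With all regularizers off, no views and uniform importance, the
        sweep must coincide per-iteration with the classical multiplicative
        NMF updates (sequential U then V), coded independently here."""
        hp = Hyperparams(lam=0.0, mu=0.0, gamma=0.0, delta=1.0)
        A_bar = rng.random((6, 4)) + 0.05
        U = rng.random((6, 2)) + 0.05
        V = rng.random((4, 2)) + 0.05
        Uo, Vo = U.copy(), V.copy()
        inst = dict(
            U=U, V=V, PLs=[], PPs=[], alpha=np.zeros(0), beta=np.zeros(0),
            A_bar=A_bar, C=np.ones((6, 4)), lnc_views=[], prot_views=[],
            SL=np.zeros((6, 6)), SP=np.zeros((4, 4)),
            D_l=np.zeros((6, 6)), D_p=np.zeros((4, 4)),
        )
        for _ in range(20):
            inst["U"], inst["V"], _, _ = _sweep(inst, hp)
            Uo = Uo * (A_bar @ Vo) / (Uo @ (Vo.T @ Vo))
            Vo = Vo * (A_bar.T @ Uo) / (Vo @ (Uo.T @ Uo))
            np.testing.assert_allclose(inst["U"], Uo, atol=1e-8)
            np.testing.assert_allclose(inst["V"], Vo, atol=1e-8)

    def test_nonnegativity_preserved_each_sweep(self, rng):
        hp = Hyperparams()
        inst = _random_instance(rng)
        for _ in range(10):
            inst["U"], inst["V"], inst["PLs"], inst["PPs"] = _sweep(inst, hp)
            for M in [inst["U"], inst["V"], *inst["PLs"], *inst["PPs"]]:
                assert np.all(M >= 0)


class TestViewWeights:
    def test_single_view(self):
        np.testing.assert_array_equal(update_view_weights(np.array([3.0]), 5.0), [1.0])

    def test_equal_residuals_uniform(self):
        np.testing.assert_allclose(
            update_view_weights(np.array([2.0, 2.0, 2.0]), 4.0), np.full(3, 1 / 3)
        )

    def test_hand_value_eta_five(self):
        # residuals (1, 16), exponent 1/4 -> unnormalized (1, 0.5)
        np.testing.assert_allclose(
            update_view_weights(np.array([1.0, 16.0]), 5.0), [2 / 3, 1 / 3]
        )

    def test_matches_simplex_grid_minimization(self):
        """The closed form must minimize 1/2 sum a_i alpha_i^eta over the
        simplex; checked against a fine grid search for two views."""
        a = np.array([1.0, 16.0])
        eta = 5.0
        grid = np.linspace(0, 1, 20001)
        vals = 0.5 * (a[0] * grid**eta + a[1] * (1 - grid) ** eta)
        best = grid[np.argmin(vals)]
        alpha = update_view_weights(a, eta)
        assert alpha[0] == pytest.approx(best, abs=1e-4)

    def test_zero_residual_limit(self):
        out = update_view_weights(np.array([0.0, 1.0, 0.0]), 5.0)
        np.testing.assert_allclose(out, [0.5, 0.0, 0.5])

    def test_noisier_duplicate_view_gets_less_weight(self, rng):
        """Adding large noise to a copy of a view increases its residual
        and must strictly decrease its weight."""
        F = rng.random((10, 4))
        P = rng.random((3, 4))
        U = F @ P.T
        clean = np.sum((F @ P.T - U) ** 2) + 1e-6
        noisy_F = F + rng.normal(scale=2.0, size=F.shape)
        noisy = np.sum((noisy_F @ P.T - U) ** 2)
        alpha = update_view_weights(np.array([clean, noisy]), 5.0)
        assert alpha[0] > alpha[1]


def _toy_model(rng, n_l=12, n_p=6, d_true=3, hp=None):
    U0 = rng.random((n_l, d_true))
    V0 = rng.random((n_p, d_true))
    scores = U0 @ V0.T
    A = (scores > np.quantile(scores, 0.75)).astype(float)
    lnc_views = [np.clip(U0 + 0.05 * rng.random(U0.shape), 0, 1)]
    prot_views = [np.clip(V0 + 0.05 * rng.random(V0.shape), 0, 1)]
    SL = np.corrcoef(U0)
    SL = np.clip(0.5 * (SL + 1), 0, 1)
    np.fill_diagonal(SL, 1.0)
    SP = np.corrcoef(V0)
    SP = np.clip(0.5 * (SP + 1), 0, 1)
    np.fill_diagonal(SP, 1.0)
    return ProjectedGraphNMF(
        A, lnc_views, prot_views, SL, SP, hyperparams=hp or Hyperparams(d=d_true)
    )


class TestFit:
    def test_same_seed_bit_identical(self, rng):
        m = _toy_model(rng)
        r1 = m.fit(seed=5)
        r2 = m.fit(seed=5)
        assert np.array_equal(r1.U, r2.U) and np.array_equal(r1.V, r2.V)
        assert r1.trace.objective == r2.trace.objective

    def test_reconstruction_improves_on_planted_data(self):
        """On noiseless planted data in the low-regularization regime the
        final weighted reconstruction error must be well below the error
        of the random initialization (ratio < 0.1, averaged over seeds)."""
        ratios = []
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            hp = Hyperparams(lam=0.01, mu=0.01, gamma=0.01, max_iter=400)
            U0 = rng.random((20, 3))
            V0 = rng.random((8, 3))
            scores = U0 @ V0.T
            A = (scores > np.quantile(scores, 0.8)).astype(float)
            m = ProjectedGraphNMF(
                A, [], [], np.eye(20), np.eye(8), A_bar=A, hyperparams=hp
            )
            init_rng = np.random.default_rng(seed)
            Ui = init_rng.uniform(size=(20, 8))
            Vi = init_rng.uniform(size=(8, 8))
            init_err = np.linalg.norm(A - Ui @ Vi.T)
            res = m.fit(seed=seed)
            ratios.append(np.linalg.norm(A - res.U @ res.V.T) / init_err)
        assert np.mean(ratios) < 0.1

    def test_objective_trace_eventually_monotone(self, rng):
        m = _toy_model(rng)
        res = m.fit(seed=3)
        tr = np.array(res.trace.objective)
        rel_increase = np.diff(tr[3:]) / np.abs(tr[3:-1])
        assert np.all(rel_increase < 1e-6)

    def test_simplex_maintained_every_iteration(self, rng):
        m = _toy_model(rng)
        res = m.fit(seed=2)
        for a, b in zip(res.trace.alpha, res.trace.beta):
            assert np.all(a >= 0) and np.all(b >= 0)
            assert a.sum() == pytest.approx(1.0)
            assert b.sum() == pytest.approx(1.0)

    def test_latent_dimension_capped(self, rng):
        m = _toy_model(rng, hp=Hyperparams(d=100, max_iter=5))
        res = m.fit(seed=0)
        assert res.U.shape[1] == min(12, 6)

    def test_summary_mentions_key_quantities(self, rng):
        m = _toy_model(rng)
        res = m.fit(seed=1)
        text = res.summary()
        assert "view weights" in text and "objective" in text

    def test_save_roundtrip(self, rng, tmp_path):
        m = _toy_model(rng)
        res = m.fit(seed=1)
        res.save(tmp_path / "model")
        import json

        sidecar = json.loads((tmp_path / "model" / "model.json").read_text())
        assert sidecar["hyperparams"]["eta"] == 5.0
        assert len(sidecar["objective_trace"]) == res.n_iter


class TestCompleteLatent:
    def test_interacting_rows_unchanged(self, rng):
        U = rng.random((4, 2))
        V = rng.random((3, 2))
        A = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [0, 0, 0]])
        SL = np.eye(4)
        SL[3, 0] = SL[0, 3] = 0.9
        U_t, V_t = complete_latent(U, V, A, SL, np.eye(3))
        np.testing.assert_array_equal(U_t[:3], U[:3])
        np.testing.assert_array_equal(V_t, V)

    def test_single_nonzero_neighbor_copied_exactly(self, rng):
        U = rng.random((3, 2))
        V = rng.random((2, 2))
        A = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
        SL = np.eye(3)
        SL[2, 1] = SL[1, 2] = 0.7  # only neighbor with nonzero similarity
        U_t, _ = complete_latent(U, V, A, SL, np.eye(2))
        np.testing.assert_allclose(U_t[2], U[1])

    def test_weighted_average_hand_value(self, rng):
        U = rng.random((3, 2))
        V = rng.random((2, 2))
        A = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
        SL = np.eye(3)
        SL[2, 0] = SL[0, 2] = 0.6
        SL[2, 1] = SL[1, 2] = 0.4
        U_t, _ = complete_latent(U, V, A, SL, np.eye(2), K=2)
        np.testing.assert_allclose(U_t[2], 0.6 * U[0] + 0.4 * U[1])

    def test_no_donors_rejected(self, rng):
        with pytest.raises(ValueError):
            complete_latent(
                rng.random((2, 2)), rng.random((2, 2)), np.zeros((2, 2)),
                np.eye(2), np.eye(2),
            )


class TestPredict:
    def test_zero_factors_zero_scores(self, rng):
        m = _toy_model(rng)
        res = m.fit(seed=1)
        res.U = np.zeros_like(res.U)
        res.V = np.zeros_like(res.V)
        np.testing.assert_array_equal(res.predict(complete=False), 0.0)

    def test_score_rank_bounded_by_latent_dim(self, rng):
        m = _toy_model(rng)
        res = m.fit(seed=1)
        Y = res.predict(complete=False)
        assert np.linalg.matrix_rank(Y) <= res.U.shape[1]

    def test_scores_nonnegative(self, rng):
        m = _toy_model(rng)
        Y = m.fit(seed=4).predict()
        assert Y.min() >= 0


class TestHyperparams:
    @pytest.mark.parametrize(
        "kwargs", [dict(eta=1.0), dict(delta=0.5), dict(d=0), dict(mu=-1.0)]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Hyperparams(**kwargs)
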