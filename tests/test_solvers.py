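import numpy as np
import pytest
from scipy.sparse.linalg import cg, LinearOperator

from sidemc.operators import ObservedMask, SideMatrices, project_observed, vec, unvec
from sidemc.solvers import (
    Hyperparameters,
    IterationWorkspace,
    ProblemData,
    SolverState,
    _xtgy,
    fit_classic_mc,
    fit_ladmm,
    fit_stoladmm,
    full_gradient_g,
    stochastic_gradient_g,
    update_C,
    update_E,
    update_G,
    update_multipliers,
)
from sidemc.evaluation import rmse_missing
from sidemc.synthetic import generate_problem


def _random_state(rng, data):
    m, n = data.m, data.n
    a, b = data.sides.a, data.sides.b
    return SolverState(
        E=rng.standard_normal((m, n)),
        G=rng.standard_normal((a, b)),
        C=rng.standard_normal((m, n)),
        M1=rng.standard_normal((m, n)),
        M2=rng.standard_normal((m, n)),
    )


@pytest.fixture
def small_data(rng):
    F = rng.standard_normal((3, 3))
    mask = ObservedMask(rng.random((3, 3)) < 0.7)
    F = np.where(mask.observed, F, np.nan)
    return ProblemData.from_arrays(F, rng.standard_normal((2, 3)), rng.standard_normal((2, 3)), mask)


class TestUpdateC:
    def test_zero_residual_gives_zero(self, small_data):
        hp = Hyperparameters(beta=0.5)
        rng = np.random.default_rng(0)
        state = _random_state(rng, small_data)
        state.E = _xtgy(small_data.sides, state.G)
        state.M2 = np.zeros_like(state.E)
        assert np.allclose(update_C(state, small_data, hp), 0.0)

    def test_large_beta_limit(self, small_data, rng):
        state = _random_state(rng, small_data)
        hp = Hyperparameters(beta=1e12)
        target = state.E - _xtgy(small_data.sides, state.G) + state.M2 / hp.beta
        assert np.allclose(update_C(state, small_data, hp), target, rtol=1e-10)

    def test_matches_quadratic_minimizer_by_cg(self, small_data, rng):
        """The closed form equals the CG solution of the C-subproblem normal equations."""
        hp = Hyperparameters(beta=0.37)
        state = _random_state(rng, small_data)
        D = state.E - _xtgy(small_data.sides, state.G)
        # minimize 1/2||C||^2 + <M2, D - C> + beta/2 ||D - C||^2
        # => (1 + beta) C = M2 + beta D, solved iteratively as a linear system
        n = D.size
        A = LinearOperator((n, n), matvec=lambda x: (1 + hp.beta) * x)
        rhs = (state.M2 + hp.beta * D).ravel()
        sol, info = cg(A, rhs, rtol=1e-12)
        assert info == 0
        assert np.allclose(update_C(state, small_data, hp), sol.reshape(D.shape), atol=1e-8)


class TestGradients:
    def test_zero_residual_gradient(self, small_data, rng):
        state = _random_state(rng, small_data)
        from sidemc.operators import kron_row_block

        ws = IterationWorkspace()
        ws.row_indices = np.arange(9)
        ws.Ak = kron_row_block(small_data.sides, ws.row_indices)
        ws.b_tilde = ws.Ak @ vec(state.G)
        assert np.allclose(stochastic_gradient_g(ws, state), 0.0, atol=1e-12)

    def test_full_sampling_matches_dense_oracle(self, small_data, rng):
        state = _random_state(rng, small_data)
        B = rng.standard_normal((3, 3))
        dense = np.kron(small_data.sides.Y.T, small_data.sides.X.T)
        oracle = dense.T @ (dense @ vec(state.G) - vec(B))
        from sidemc.operators import kron_row_block

        ws = IterationWorkspace()
        ws.row_indices = np.arange(9)
        ws.Ak = kron_row_block(small_data.sides, ws.row_indices)
        ws.b_tilde = vec(B)
        assert np.allclose(stochastic_gradient_g(ws, state), oracle, atol=1e-10)
        assert np.allclose(full_gradient_g(state, B, small_data.sides), oracle, atol=1e-10)

    def test_sampling_expectation_scales_full_gradient(self, small_data, rng):
        """E[f1] over resamples = (s/nm) * full gradient (plain-sum convention)."""
        from sidemc.operators import kron_row_block

        state = _random_state(rng, small_data)
        B = rng.standard_normal((3, 3))
        full = full_gradient_g(state, B, small_data.sides)
        s, nm = 3, 9
        acc = np.zeros_like(full)
        n_rep = 2000
        for _ in range(n_rep):
            ws = IterationWorkspace()
            ws.row_indices = rng.choice(nm, size=s, replace=False)
            ws.Ak = kron_row_block(small_data.sides, ws.row_indices)
            ws.b_tilde = vec(B)[ws.row_indices]
            acc += stochastic_gradient_g(ws, state)
        mean = acc / n_rep
        target = (s / nm) * full
        assert np.linalg.norm(mean - target) < 0.05 * max(np.linalg.norm(target), 1.0)

    def test_parallel_shards_match_sequential(self, small_data, rng):
        from sidemc.operators import kron_row_block

        state = _random_state(rng, small_data)
        ws = IterationWorkspace()
        ws.row_indices = np.arange(9)
        ws.Ak = kron_row_block(small_data.sides, ws.row_indices)
        ws.b_tilde = rng.standard_normal(9)
        seq = stochastic_gradient_g(ws, state, n_jobs=1)
        par = stochastic_gradient_g(ws, state, n_jobs=3)
        assert np.allclose(seq, par, atol=1e-12)


class TestProximalSteps:
    def test_update_g_fixed_point_and_pure_gradient(self, small_data, rng):
        state = _random_state(rng, small_data)
        state.G = np.zeros_like(state.G)
        ws = IterationWorkspace(f1=np.zeros(state.G.size))
        hp = Hyperparameters(lambda_G=1.0, beta=0.5)
        assert np.allclose(update_G(state, ws, hp, tau=2.0), 0.0)
        hp0 = Hyperparameters(lambda_G=0.0, beta=0.5)
        state2 = _random_state(rng, small_data)
        ws2 = IterationWorkspace(f1=rng.standard_normal(state2.G.size))
        expected = vec(state2.G) - ws2.f1 / 3.0
        assert np.allclose(vec(update_G(state2, ws2, hp0, tau=3.0)), expected)

    def test_update_g_matches_separable_grid_oracle(self, small_data, rng):
        """update_G equals the componentwise minimizer of
        lambda_G|g| + beta*tau/2 (g - z)^2 found by dense 1-D grid search."""
        state = _random_state(rng, small_data)
        hp = Hyperparameters(lambda_G=0.7, beta=0.4)
        tau = 1.9
        ws = IterationWorkspace(f1=rng.standard_normal(state.G.size))
        z = vec(state.G) - ws.f1 / tau
        grid = np.linspace(-6, 6, 48001)
        oracle = np.empty_like(z)
        for i, zi in enumerate(z):
            objective = hp.lambda_G * np.abs(grid) + 0.5 * hp.beta * tau * (grid - zi) ** 2
            oracle[i] = grid[np.argmin(objective)]
        assert np.allclose(vec(update_G(state, ws, hp, tau)), oracle, atol=1e-3)

    def test_update_g_rejects_bad_tau(self, small_data, rng):
        state = _random_state(rng, small_data)
        ws = IterationWorkspace(f1=np.zeros(state.G.size))
        with pytest.raises(ValueError):
            update_G(state, ws, Hyperparameters(), tau=0.0)

    def test_update_e_fixed_point(self, small_data, rng):
        state = _random_state(rng, small_data)
        ws = IterationWorkspace(f2=np.zeros((3, 3)), f3=np.zeros((3, 3)))
        hp = Hyperparameters(lambda_E=0.0)
        assert np.allclose(update_E(state, ws, hp, tau_prime=1.0), state.E, atol=1e-10)

    def test_f2_vanishes_when_constraint_met(self, small_data, rng):
        state = _random_state(rng, small_data)
        state.E = np.where(small_data.mask.observed, small_data.F, state.E)
        state.M1 = np.zeros((3, 3))
        hp = Hyperparameters()
        f2 = project_observed(state.E - small_data.F_observed + state.M1 / hp.beta, small_data.mask)
        assert np.allclose(f2, 0.0)

    def test_update_e_matches_svd_prox_oracle(self, rng):
        """On 4x4 inputs the E step equals the nuclear-norm prox computed from
        an independently coded full SVD."""
        F = rng.standard_normal((4, 4))
        mask = ObservedMask(np.ones((4, 4), dtype=bool))
        data = ProblemData.from_arrays(F, rng.standard_normal((2, 4)), rng.standard_normal((2, 4)), mask)
        state = _random_state(rng, data)
        ws = IterationWorkspace(
            f2=rng.standard_normal((4, 4)), f3=rng.standard_normal((4, 4))
        )
        hp = Hyperparameters(lambda_E=0.8, beta=0.3)
        tau_p = 1.7
        point = state.E - (ws.f2 + ws.f3) / (2 * tau_p)
        thr = hp.lambda_E / (2 * hp.beta * tau_p)
        U, s, Vt = np.linalg.svd(point, full_matrices=False)
        oracle = (U * np.maximum(s - thr, 0.0)) @ Vt
        assert np.allclose(update_E(state, ws, hp, tau_p), oracle, atol=1e-10)

    def test_update_e_rejects_bad_tau(self, small_data, rng):
        state = _random_state(rng, small_data)
        ws = IterationWorkspace(f2=np.zeros((3, 3)), f3=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            update_E(state, ws, Hyperparameters(), tau_prime=-1.0)


class TestMultipliers:
    def test_zero_residuals_leave_multipliers(self, small_data, rng):
        state = _random_state(rng, small_data)
        state.E = np.where(small_data.mask.observed, small_data.F, 0.0)
        state.C = state.E - _xtgy(small_data.sides, state.G)
        M1, M2 = update_multipliers(state, small_data, Hyperparameters(beta=0.5))
        assert np.allclose(M1, state.M1) and np.allclose(M2, state.M2)

    def test_unit_residual_arithmetic(self, rng):
        F = np.zeros((2, 2))
        mask = ObservedMask.from_pairs([(0, 0)], (2, 2))
        data = ProblemData.from_arrays(F, np.zeros((1, 2)), np.zeros((1, 2)), mask)
        state = SolverState(
            E=np.ones((2, 2)),
            G=np.zeros((2, 2)),
            C=np.zeros((2, 2)),
            M1=np.zeros((2, 2)),
            M2=np.zeros((2, 2)),
        )
        M1, M2 = update_multipliers(state, data, Hyperparameters(beta=0.5))
        assert M1[0, 0] == pytest.approx(0.5) and M1[1, 1] == 0.0
        assert np.allclose(M2, 0.5)


class TestSubobjectiveDecrease:
    def test_each_update_weakly_decreases_its_subobjective(self, tiny_problem):
        """With a safely majorizing proximal parameter (tau_safety > 1), each
        linearized step cannot increase its own augmented-Lagrangian piece."""
        data = tiny_problem.data
        hp = Hyperparameters(lambda_E=0.5, lambda_G=0.5, beta=0.1, tau_safety=1.01, seed=3)
        rng = np.random.default_rng(5)
        state = _random_state(rng, data)
        sides = data.sides
        from sidemc.operators import operator_norm

        opn = operator_norm(sides)
        for _ in range(5):
            state.C = update_C(state, data, hp)
            B = state.E + state.M2 / hp.beta - state.C

            def g_obj(G):
                r = _xtgy(sides, G) - B
                return hp.lambda_G * np.abs(G).sum() + 0.5 * hp.beta * np.sum(r * r)

            ws = IterationWorkspace(f1=full_gradient_g(state, B, sides))
            tau = hp.tau_safety * opn**2
            G_new = update_G(state, ws, hp, tau)
            assert g_obj(G_new) <= g_obj(state.G) + 1e-8 * (1 + abs(g_obj(state.G)))
            state.G = G_new
            XtGY = _xtgy(sides, state.G)
            ws.B2 = project_observed(data.F_observed - state.M1 / hp.beta, data.mask)
            ws.B3 = XtGY + state.C - state.M2 / hp.beta
            ws.f2 = project_observed(state.E - data.F_observed + state.M1 / hp.beta, data.mask)
            ws.f3 = state.E - ws.B3

            def e_obj(E):
                nuc = np.linalg.svd(E, compute_uv=False).sum()
                r2 = project_observed(E - ws.B2, data.mask)
                r3 = E - ws.B3
                return hp.lambda_E * nuc + 0.5 * hp.beta * (np.sum(r2 * r2) + np.sum(r3 * r3))

            E_new = update_E(state, ws, hp, hp.tau_safety)
            assert e_obj(E_new) <= e_obj(state.E) + 1e-8 * (1 + abs(e_obj(state.E)))
            state.E = E_new
            state.M1, state.M2 = update_multipliers(state, data, hp, xtgy=XtGY)


class TestFits:
    def test_stoladmm_recovers_tiny_noiseless(self, tiny_noiseless_problem):
        p = tiny_noiseless_problem
        hp = Hyperparameters(lambda_E=1e-2, lambda_G=1e-2, max_iter=8000, seed=2)
        res = fit_stoladmm(p.data, hp)
        pred = res.predicted(p.data.sides)
        assert rmse_missing(pred, p.true_F, ~p.data.mask.observed) < 1e-2

    def test_large_lambda_g_degenerates_to_classic_mc(self, tiny_problem):
        p = tiny_problem
        hp = Hyperparameters(lambda_E=1.0, lambda_G=1e8, max_iter=800, seed=2)
        res = fit_stoladmm(p.data, hp)
        assert np.abs(res.G).max() < 1e-6
        E_classic = fit_classic_mc(p.data.F, p.data.mask, 1.0, max_iter=800)
        rel = np.linalg.norm(res.E - E_classic) / np.linalg.norm(E_classic)
        assert rel < 0.05

    def test_full_sampling_reproduces_ladmm(self, rng):
        p = generate_problem("I", 30, seed=5, dims=dict(m=20, n=20, d1=4, d2=5))
        hp = Hyperparameters(lambda_E=0.1, lambda_G=0.1, max_iter=40, seed=9, s=400)
        a = fit_stoladmm(p.data, hp)
        b = fit_ladmm(p.data, hp)
        assert np.allclose(a.E, b.E, atol=1e-10)
        assert np.allclose(a.G, b.G, atol=1e-10)
        assert np.allclose(a.trace["objective"], b.trace["objective"], rtol=1e-10)

    def test_seed_determinism(self, tiny_problem):
        hp = Hyperparameters(lambda_E=0.1, lambda_G=0.1, max_iter=30, seed=42)
        a = fit_stoladmm(tiny_problem.data, hp)
        b = fit_stoladmm(tiny_problem.data, hp)
        assert np.array_equal(a.E, b.E) and np.array_equal(a.G, b.G)

    def test_ladmm_fully_observed_matches_f(self, rng):
        p = generate_problem("I", 0, seed=6, dims=dict(m=15, n=15, d1=3, d2=3))
        hp = Hyperparameters(lambda_E=1e-4, lambda_G=1e-4, max_iter=3000, tol=1e-7, seed=1)
        res = fit_ladmm(p.data, hp)
        assert np.allclose(res.E, p.true_F, atol=1e-2 * np.abs(p.true_F).max())

    def test_constraint_residuals_vanish_at_convergence(self, tiny_problem):
        hp = Hyperparameters(lambda_E=1e-2, lambda_G=1e-2, max_iter=4000, tol=1e-5, seed=2)
        res = fit_ladmm(tiny_problem.data, hp)
        last = res.trace.iloc[-1]
        assert res.converged
        assert last["residual_obs"] < 1e-5 and last["residual_couple"] < 1e-5

    def test_sparsity_monotone_in_lambda_g(self):
        p = generate_problem("I", 20, seed=8, dims=dict(m=30, n=30, d1=4, d2=4), density=0.5)
        nnz = []
        for lam_g in [1e-2, 1.0, 1e2, 1e4]:
            hp = Hyperparameters(lambda_E=0.1, lambda_G=lam_g, max_iter=300, seed=3)
            res = fit_ladmm(p.data, hp)
            nnz.append(int((np.abs(res.G) > 1e-10).sum()))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))
        assert nnz[0] > nnz[-1]


class TestClassicMC:
    def test_rank_one_recovery(self, rng):
        u, v = rng.standard_normal(20), rng.standard_normal(20)
        F = np.outer(u, v)
        mask = ObservedMask(rng.random((20, 20)) < 0.8)
        E = fit_classic_mc(F, mask, lambda_E=5 * np.sqrt(400), max_iter=2000, tol=1e-9)
        miss = ~mask.observed
        assert rmse_missing(E, F, miss) < 1e-3

    def test_fully_observed_returns_f(self, rng):
        F = rng.standard_normal((10, 10))
        mask = ObservedMask(np.ones((10, 10), dtype=bool))
        E = fit_classic_mc(F, mask, lambda_E=1.0, max_iter=2000, tol=1e-10)
        assert np.allclose(E, F, atol=1e-6 * np.abs(F).max())

    def test_zero_matrix_fixed_point(self):
        mask = ObservedMask(np.ones((5, 5), dtype=bool))
        assert np.allclose(fit_classic_mc(np.zeros((5, 5)), mask, 1.0), 0.0)

    def test_empty_mask_rejected(self):
        mask = ObservedMask(np.zeros((3, 3), dtype=bool))
        with pytest.raises(ValueError):
            fit_classic_mc(np.zeros((3, 3)), mask, 1.0)


class TestHyperparameters:
    def test_default_s_formula(self):
        assert Hyperparameters.default_s(16, 21) == max(1, round(np.sqrt(16 * 21 / 100)))
        assert Hyperparameters.default_s(1, 1) == 1

    @pytest.mark.parametrize(
        "kw",
        [dict(beta=0.0), dict(beta=-1.0), dict(s=0), dict(max_iter=0), dict(tol=0.0),
         dict(lambda_E=-0.1), dict(tau_policy="bogus")],
    )
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ValueError):
            Hyperparameters(**kw)
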