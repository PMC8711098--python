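import numpy as np
import pytest
from scipy import optimize

from mlaprbfn import generate_multiview_fixture, kfold_cv
from mlaprbfn.cohort import standardize
from mlaprbfn.graphs import build_view_graphs, fuse
from mlaprbfn.rbf import design_matrix, fit_rbfn, fit_rbfn_model, make_basis
from mlaprbfn.solver import (
    Hyperparams,
    MLapRBFNModel,
    fit_mlaprbfn,
    objective,
    update_G,
    update_W,
    update_eta,
)


def small_problem(rng, n=30, p=5, q=1, d=3):
    X = rng.normal(size=(n, d))
    basis = make_basis(X, p, seed=0)
    Phi = design_matrix(X, basis)
    Y = rng.normal(size=(n, q))
    graphs = build_view_graphs(X, kernels=(1, 2, 3), rho=2.0)
    return X, Phi, Y, graphs


class TestObjective:
    def test_zero_weights_leave_only_data_term(self, rng):
        _, Phi, Y, graphs = small_problem(rng)
        hp = Hyperparams(p=5, lambda1=1.0, lambda2=7.0, kernels=(1, 2, 3))
        J = objective(Phi, Y, np.zeros((5, 1)), graphs, hp)
        assert J == pytest.approx(0.5 * np.sum(Y**2), rel=1e-12)

    def test_unregularized_reduces_to_half_squared_residual(self, rng):
        _, Phi, Y, graphs = small_problem(rng)
        W = rng.normal(size=(5, 1))
        hp = Hyperparams(p=5, lambda1=0.0, lambda2=0.0, kernels=(1, 2, 3))
        J = objective(Phi, Y, W, graphs, hp)
        assert J == pytest.approx(0.5 * np.sum((Phi @ W - Y) ** 2), rel=1e-12)

    def test_matches_term_by_term_loop_oracle(self, rng):
        _, Phi, Y, graphs = small_problem(rng, q=2)
        W = rng.normal(size=(5, 2))
        hp = Hyperparams(p=5, lambda1=0.3, lambda2=0.7, rho=2.0, kernels=(1, 2, 3))
        fit = 0.0
        for i in range(Phi.shape[0]):
            for k in range(2):
                fit += (Phi[i] @ W[:, k] - Y[i, k]) ** 2
        F = Phi @ W
        L_star = fuse(graphs.L_list, graphs.eta, 2.0)
        lap = sum(
            F[:, k] @ L_star @ F[:, k] for k in range(2)
        )
        l21 = sum(np.sqrt(np.sum(W[j] ** 2)) for j in range(5))
        expected = 0.5 * fit + 0.5 * 0.3 * lap + 0.5 * 0.7 * l21
        assert objective(Phi, Y, W, graphs, hp) == pytest.approx(expected, rel=1e-10)


class TestUpdateG:
    def test_three_four_row(self):
        G = update_G(np.array([[3.0, 4.0]]), eps_irls=1e-8)
        assert G[0, 0] == pytest.approx(0.1, rel=1e-12)

    def test_zero_row_guarded(self):
        G = update_G(np.array([[0.0, 0.0]]), eps_irls=1e-8)
        assert G[0, 0] == pytest.approx(1.0 / (2e-8), rel=1e-12)
        assert np.isfinite(G).all()

    def test_matches_per_row_loop(self, rng):
        W = rng.normal(size=(6, 3))
        G = update_G(W, eps_irls=1e-8)
        for j in range(6):
            assert G[j, j] == pytest.approx(
                1.0 / (2 * np.linalg.norm(W[j])), rel=1e-12
            )
        assert np.count_nonzero(G - np.diag(np.diag(G))) == 0


class TestUpdateW:
    def test_unregularized_matches_closed_form_rbfn(self, rng):
        _, Phi, Y, graphs = small_problem(rng)
        L_star = fuse(graphs.L_list, graphs.eta, 2.0)
        W = update_W(Phi, Y, L_star, np.eye(5), 0.0, 0.0)
        np.testing.assert_allclose(W, fit_rbfn(Phi, Y), atol=1e-8)

    def test_solves_stationarity_system(self, rng):
        _, Phi, Y, graphs = small_problem(rng)
        L_star = fuse(graphs.L_list, graphs.eta, 2.0)
        G = update_G(rng.normal(size=(5, 1)))
        W = update_W(Phi, Y, L_star, G, 0.2, 0.4)
        A = Phi.T @ Phi + 0.2 * Phi.T @ L_star @ Phi + 0.4 * G
        assert np.linalg.norm(A @ W - Phi.T @ Y) < 1e-8 * np.linalg.norm(Phi.T @ Y)

    def test_minimizes_quadratic_surrogate_against_perturbations(self, rng):
        _, Phi, Y, graphs = small_problem(rng)
        L_star = fuse(graphs.L_list, graphs.eta, 2.0)
        G = update_G(rng.normal(size=(5, 1)))
        lam1, lam2 = 0.3, 0.5
        W = update_W(Phi, Y, L_star, G, lam1, lam2)

        def surrogate(Wm):
            F = Phi @ Wm
            return (
                0.5 * np.sum((F - Y) ** 2)
                + 0.5 * lam1 * np.trace(F.T @ L_star @ F)
                + 0.5 * lam2 * np.trace(Wm.T @ G @ Wm)
            )

        base = surrogate(W)
        for _ in range(1000):
            delta = rng.normal(scale=rng.choice([1e-3, 1e-1, 1.0]), size=W.shape)
            assert surrogate(W + delta) >= base - 1e-10

    def test_singular_system_raises_after_jitter_when_unsolvable(self):
        # an exactly singular, inconsistent system is rescued by the jitter
        Phi = np.ones((4, 2))
        W = update_W(Phi, np.ones((4, 1)), np.zeros((4, 4)), np.zeros((2, 2)), 0.0, 0.0)
        assert np.isfinite(W).all()


class TestUpdateEta:
    def test_identical_views_give_uniform_weights(self, rng):
        _, Phi, _, graphs = small_problem(rng)
        W = rng.normal(size=(5, 1))
        L = graphs.L_list[0]
        eta = update_eta(Phi, W, [L, L, L], rho=2.0)
        assert np.all(eta == 1.0 / 3.0)

    def test_traces_one_and_four_give_point_eight_point_two(self):
        # F = ones(2,1); diag Laplacians tuned so h = (1, 4)
        Phi = np.eye(2)
        W = np.ones((2, 1))
        L1 = np.diag([0.5, 0.5])
        L2 = np.diag([2.0, 2.0])
        eta = update_eta(Phi, W, [L1, L2], rho=2.0)
        np.testing.assert_array_equal(eta, [0.8, 0.2])

    def test_matches_constrained_numerical_minimizer(self, rng):
        # oracle: SLSQP minimization of sum eta^rho h on the simplex
        h = np.abs(rng.normal(size=3)) + 0.2
        Phi = np.eye(3)
        W = np.ones((3, 1))
        L_list = [np.diag(np.full(3, hv / 3.0)) for hv in h]
        eta = update_eta(Phi, W, L_list, rho=2.0)

        res = optimize.minimize(
            lambda e: np.sum(e**2 * h),
            x0=np.full(3, 1 / 3),
            constraints=[{"type": "eq", "fun": lambda e: e.sum() - 1}],
            bounds=[(1e-9, 1)] * 3,
            method="SLSQP",
            options={"ftol": 1e-14, "maxiter": 500},
        )
        np.testing.assert_allclose(eta, res.x, atol=1e-5)

    def test_entropy_nondecreasing_in_rho(self):
        # larger rho flattens eta toward uniform on fixed traces
        Phi = np.eye(3)
        W = np.ones((3, 1))
        h = np.array([0.5, 2.0, 7.0])
        L_list = [np.diag(np.full(3, hv / 3.0)) for hv in h]
        entropies = []
        for rho in (1.1, 2.0, 4.0, 16.0):
            eta = update_eta(Phi, W, L_list, rho=rho)
            entropies.append(float(-(eta * np.log(eta)).sum()))
        assert np.all(np.diff(entropies) >= -1e-12)

    def test_all_traces_clamped_warns_and_returns_uniform(self):
        Phi = np.eye(2)
        W = np.zeros((2, 1))
        L = np.eye(2)
        with pytest.warns(RuntimeWarning):
            eta = update_eta(Phi, W, [L, L], rho=2.0)
        np.testing.assert_allclose(eta, 0.5)


class TestFitMlaprbfn:
    def test_unregularized_reduces_to_plain_rbfn(self, small_fixture):
        hp = Hyperparams(p=8, seed=3, lambda1=0.0, lambda2=0.0)
        m = fit_mlaprbfn(small_fixture, hp)
        plain = fit_rbfn_model(small_fixture, p=8, seed=3)
        np.testing.assert_allclose(m.W, plain.W, atol=1e-8)
        np.testing.assert_allclose(
            m.predict(small_fixture.X), plain.predict(small_fixture.X), atol=1e-6
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_trace_monotone(self, seed):
        fx = generate_multiview_fixture(n=60, d=3, noise_sd=0.05, seed=seed)
        m = fit_mlaprbfn(fx, Hyperparams(p=8, seed=seed))
        tr = np.asarray(m.state.objective_trace)
        assert np.all(np.diff(tr) <= 1e-9 * np.abs(tr[:-1]))

    def test_eta_on_open_simplex_every_iteration(self, small_fixture):
        m = fit_mlaprbfn(small_fixture, Hyperparams(p=8, seed=1))
        for eta in m.state.eta_trace:
            assert abs(eta.sum() - 1.0) < 1e-12
            assert np.all((eta > 0) & (eta < 1))

    def test_identical_views_fuse_to_shrunk_single_view(self, rng):
        # algebraic identity: V copies at eta=1/V fuse to V^(1-rho) L
        L = np.diag(rng.uniform(0.5, 2.0, size=4))
        for V, rho in [(2, 2.0), (4, 2.0), (3, 3.0)]:
            fused = fuse([L] * V, np.full(V, 1.0 / V), rho)
            np.testing.assert_allclose(fused, V ** (1.0 - rho) * L, atol=1e-14)

    def test_p_larger_than_cohort_rejected(self, small_fixture):
        with pytest.raises(ValueError):
            fit_mlaprbfn(small_fixture, Hyperparams(p=200, seed=0))

    def test_regularization_helps_in_overfitting_regime(self):
        # many centers + strong noise: the graph/L21 penalties cut LS variance
        wins = 0
        for seed in range(10):
            fx = generate_multiview_fixture(n=60, d=3, noise_sd=0.5, seed=seed)
            hp = Hyperparams(p=30, seed=seed)
            rm = kfold_cv(fx, 10, seed, hp, "mlaprbfn")
            rb = kfold_cv(fx, 10, seed, hp, "rbfn")
            wins += rm.metrics.rmse <= rb.metrics.rmse
        assert wins >= 6

    def test_early_stop_option(self, small_fixture):
        hp = Hyperparams(p=8, seed=0, tmax=50, tol_objective=1e-6)
        m = fit_mlaprbfn(small_fixture, hp)
        assert len(m.state.objective_trace) < 51


class TestModelSerialization:
    def test_json_round_trip_preserves_predictions(self, tmp_path, small_fixture):
        m = fit_mlaprbfn(small_fixture, Hyperparams(p=8, seed=2))
        path = tmp_path / "model.json"
        m.to_json(path)
        back = MLapRBFNModel.from_json(path)
        np.testing.assert_allclose(
            back.predict(small_fixture.X), m.predict(small_fixture.X), atol=1e-12
        )
        np.testing.assert_allclose(back.eta, m.eta, atol=1e-15)


def test_hyperparams_validation():
    with pytest.raises(ValueError):
        Hyperparams(rho=1.0)
    with pytest.raises(ValueError):
        Hyperparams(lambda1=-0.1)
    with pytest.raises(ValueError):
        Hyperparams(kernels=(1, 9))
    with pytest.raises(ValueError):
        Hyperparams(tmax=0)
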