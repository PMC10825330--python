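"""Surrogate network: forward pass, LM training, influence analysis."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from uaextract.ann import (
    NetworkParams,
    ScalingSpec,
    TrainingConfig,
    _init_params,
    _jacobian,
    _lm_step,
    forward,
    forward_scaled,
    logsig,
    relative_influence,
    select_hidden_neurons,
    train_lm,
)
from uaextract.fixtures import load_network_params


def random_params(n_in, n_h, n_out, rng, scale=1.0):
    return NetworkParams(
        rng.normal(0, scale, (n_h, n_in)),
        rng.normal(0, scale, n_h),
        rng.normal(0, scale, (n_out, n_h)),
        rng.normal(0, scale, n_out),
    )


class TestForward:
    def test_zero_parameters_give_scaled_half(self):
        # with all weights zero every hidden unit is logsig(0) = 0.5 and the
        # output is logsig(0) = 0.5 regardless of the input
        p = NetworkParams(np.zeros((3, 2)), np.zeros(3), np.zeros((2, 3)), np.zeros(2))
        _, ys = forward_scaled(p, np.array([[0.1, 0.9], [0.5, 0.5]]))
        assert np.allclose(ys, 0.5)
        assert logsig(np.array(0.0)) == pytest.approx(0.5)

    def test_hand_evaluated_1_1_1_composition(self):
        # u=1, th=0, w=1, to=0, scaled input 0: hidden = 0.5, out = logsig(0.5)
        p = NetworkParams([[1.0]], [0.0], [[1.0]], [0.0])
        h, ys = forward_scaled(p, np.array([[0.0]]))
        assert h[0, 0] == pytest.approx(0.5)
        assert ys[0, 0] == pytest.approx(0.62246, abs=1e-5)

    def test_scaled_outputs_strictly_inside_unit_interval(self, rng):
        p = random_params(4, 12, 4, rng, scale=3.0)
        _, ys = forward_scaled(p, rng.uniform(-2, 2, (50, 4)))
        assert np.all((ys > 0) & (ys < 1))

    def test_natural_forward_inverts_scaling(self, rng):
        p = random_params(2, 3, 2, rng)
        scaling = ScalingSpec([0, 0], [1, 1], [10, 100], [20, 200])
        y = forward(p, scaling, np.array([0.5, 0.5]))
        lo = scaling.unscale_out(np.array([0.0, 0.0]))
        hi = scaling.unscale_out(np.array([1.0, 1.0]))
        assert np.all(y > lo) and np.all(y < hi)

    def test_dimension_mismatch_raises(self, rng):
        p = random_params(4, 3, 2, rng)
        with pytest.raises(ValueError, match="inputs"):
            forward_scaled(p, np.zeros((1, 3)))


class TestJacobian:
    @pytest.mark.parametrize("shape", [(2, 3, 2), (4, 5, 4), (1, 1, 1)])
    def test_matches_central_finite_differences(self, shape, rng):
        n_in, n_h, n_out = shape
        p = random_params(n_in, n_h, n_out, rng)
        X = rng.uniform(0.05, 0.95, (7, n_in))
        J, _ = _jacobian(p, X)
        vec = p.to_vector()
        eps = 1e-6
        J_fd = np.empty_like(J)
        for j in range(vec.size):
            vp, vm = vec.copy(), vec.copy()
            vp[j] += eps
            vm[j] -= eps
            _, yp = forward_scaled(NetworkParams.from_vector(vp, *shape), X)
            _, ym = forward_scaled(NetworkParams.from_vector(vm, *shape), X)
            J_fd[:, j] = ((yp - ym) / (2 * eps)).ravel()
        scale = max(1.0, np.abs(J_fd).max())
        assert np.abs(J - J_fd).max() / scale < 1e-6

    def test_lm_step_limits(self, rng):
        """mu -> 0 gives the Gauss-Newton step; mu -> inf a scaled gradient step.

        Checked on a full-rank two-parameter least-squares problem, where
        the Gauss-Newton step is the unique normal-equations solution.
        """
        J = rng.normal(size=(20, 2))
        r = rng.normal(size=20)
        g = J.T @ r
        gn = np.linalg.solve(J.T @ J, -g)
        assert np.allclose(_lm_step(J.T @ J, g, 1e-12), gn, rtol=1e-8)
        mu = 1e12
        assert np.allclose(_lm_step(J.T @ J, g, mu), -g / mu, rtol=1e-4)


class TestTrainLM:
    def test_two_patterns_exactly_fittable(self):
        # two patterns, two hidden units: LM should interpolate to machine noise
        net = train_lm(
            X=np.array([[0.3], [0.8]]), Y=np.array([[0.7], [0.2]]),
            config=TrainingConfig(max_cycles=500, split=(1.0, 0.0, 0.0), seed=0),
            hidden_n=2,
        )
        assert net.history["train_mse"][-1] < 1e-10

    def test_accepted_sse_sequence_non_increasing(self, noisy_design):
        net = train_lm(noisy_design, TrainingConfig(max_cycles=60, seed=3), hidden_n=5)
        mse = np.array(net.history["train_mse"])
        assert np.all(np.diff(mse) <= 1e-15)

    def test_noiseless_surface_high_training_r2(self, noiseless_design):
        net = train_lm(noiseless_design, TrainingConfig(max_cycles=2000, seed=1), hidden_n=12)
        assert net.r2["train"] >= 0.99

    def test_deterministic_given_seed(self, noisy_design):
        cfg = TrainingConfig(max_cycles=40, seed=11)
        a = train_lm(noisy_design, cfg, hidden_n=4)
        b = train_lm(noisy_design, cfg, hidden_n=4)
        assert np.array_equal(a.params.to_vector(), b.params.to_vector())

    @pytest.mark.parametrize("init_seed", [7, 8, 9])
    def test_matches_scipy_lm_oracle_on_tiny_problem(self, init_seed):
        """scipy's LM, started from the same point on the identical scaled
        residual, reaches the same interpolation floor as our trainer."""
        shape = (1, 2, 1)
        teacher = random_params(*shape, rng=np.random.default_rng(5), scale=0.5)
        X = np.linspace(0.05, 0.95, 25)[:, None]
        _, Y = forward_scaled(teacher, X)  # already in (0,1): identity scaling
        identity = ScalingSpec([0.0], [1.0], [0.0], [1.0], lo=0.0, hi=1.0)

        def resid(vec):
            _, ys = forward_scaled(NetworkParams.from_vector(vec, *shape), X)
            return (ys - Y).ravel()

        x0 = _init_params(*shape, np.random.default_rng(init_seed))
        oracle = least_squares(
            resid, x0.to_vector(), method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15
        )
        net = train_lm(
            X=X, Y=Y,
            config=TrainingConfig(max_cycles=3000, split=(1.0, 0.0, 0.0), seed=0),
            init_params=x0, scaling=identity,
        )
        assert net.history["train_mse"][-1] * Y.size < 1e-12
        assert 2 * oracle.cost < 1e-12

    @pytest.mark.parametrize("teacher_seed", [2, 5, 9])
    def test_teacher_network_function_recovery(self, teacher_seed):
        """Noiseless data from a teacher net is recovered in function space.

        The student shares the teacher's (identity) scaling and has spare
        capacity; weights need not match (hidden-unit permutation symmetry)
        but the function must, so the held-out MSE collapses.
        """
        shape = (2, 3, 2)
        teacher = random_params(*shape, rng=np.random.default_rng(teacher_seed), scale=0.8)
        rng = np.random.default_rng(3)
        X = rng.uniform(0.05, 0.95, (80, 2))
        _, Y = forward_scaled(teacher, X)
        identity = ScalingSpec([0.0, 0.0], [1.0, 1.0], [0.0, 0.0], [1.0, 1.0], lo=0.0, hi=1.0)
        net = train_lm(
            X=X, Y=Y,
            config=TrainingConfig(max_cycles=2000, seed=0),
            hidden_n=5, scaling=identity,
        )
        assert len(net.split["test"]) > 0
        assert net.history["test_mse"][-1] < 1e-6

    def test_too_few_rows_raise(self):
        with pytest.raises(ValueError, match="at least 2"):
            train_lm(X=np.zeros((1, 2)), Y=np.zeros((1, 1)))


class TestSelectHidden:
    def test_singleton_candidate(self, noisy_design):
        assert select_hidden_neurons(
            noisy_design, TrainingConfig(max_cycles=30, seed=0), [12]
        ) == 12

    def test_underfit_candidate_excluded(self):
        """Data from a 4-hidden teacher never selects a 2-unit network."""
        shape = (2, 4, 1)
        teacher = random_params(*shape, rng=np.random.default_rng(8), scale=2.0)
        rng = np.random.default_rng(9)
        X = rng.uniform(0.05, 0.95, (60, 2))
        _, Y = forward_scaled(teacher, X)
        choice = None
        best_err = np.inf
        for h in (2, 4, 8):
            net = train_lm(X=X, Y=Y, config=TrainingConfig(max_cycles=400, seed=1), hidden_n=h)
            err = net.history["val_mse"][-1]
            if err < best_err:
                best_err, choice = err, h
        assert choice in (4, 8)

    def test_deterministic_selection(self, noisy_design):
        cfg = TrainingConfig(max_cycles=30, seed=5)
        a = select_hidden_neurons(noisy_design, cfg, [3, 5, 7])
        b = select_hidden_neurons(noisy_design, cfg, [3, 5, 7])
        assert a == b

    def test_empty_candidates_raise(self, noisy_design):
        with pytest.raises(ValueError, match="empty"):
            select_hidden_neurons(noisy_design, candidates=[])


class TestInfluence:
    def test_single_path_product(self):
        p = NetworkParams([[2.0]], [0.0], [[3.0]], [0.0])
        table = relative_influence(p, "connection-weights")
        assert table.values.iloc[0, 0] == pytest.approx(6.0)

    def test_sign_matches_finite_difference_sensitivity(self, rng):
        p = random_params(4, 3, 2, rng)
        table = relative_influence(p, "connection-weights").values.to_numpy()
        X = rng.uniform(0.2, 0.8, (100, 4))
        eps = 1e-5
        sens = np.zeros((4, 2))
        for i in range(4):
            Xp, Xm = X.copy(), X.copy()
            Xp[:, i] += eps
            Xm[:, i] -= eps
            _, yp = forward_scaled(p, Xp)
            _, ym = forward_scaled(p, Xm)
            sens[i] = ((yp - ym) / (2 * eps)).mean(axis=0)
        strong = np.abs(table) > 0.5 * np.abs(table).max()
        assert np.all(np.sign(table[strong]) == np.sign(sens[strong]))

    def test_garson_normalizes_per_output(self, rng):
        p = random_params(4, 6, 3, rng)
        vals = relative_influence(p, "garson").values
        assert np.all(vals.to_numpy() >= 0)
        assert np.allclose(vals.sum(axis=0), 1.0)

    def test_linear_in_output_weights(self, rng):
        p = random_params(3, 4, 2, rng)
        doubled = NetworkParams(p.u, p.th, 2.0 * p.w, p.to)
        a = relative_influence(p, "connection-weights").values.to_numpy()
        b = relative_influence(doubled, "connection-weights").values.to_numpy()
        assert np.allclose(b, 2.0 * a)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError, match="method"):
            relative_influence(random_params(2, 2, 2, rng), "shapley")


class TestPublishedWeightTable:
    def test_partition_shapes_and_first_value(self):
        p = load_network_params()
        assert (p.u.shape, p.th.shape, p.w.shape, p.to.shape) == ((12, 4), (12,), (4, 12), (4,))
        assert p.n_params == 112
        assert p.u[0, 0] == pytest.approx(8.11)

    def test_forward_pass_bounded(self, rng):
        p = load_network_params()
        _, ys = forward_scaled(p, rng.uniform(0.05, 0.95, (20, 4)))
        assert np.all(np.isfinite(ys)) and np.all((ys > 0) & (ys < 1))
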