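import numpy as np
import pytest

from netgp.exceptions import TrainingDivergedError, ValidationError
from netgp.network import (
    Architecture,
    NetworkWeights,
    TrainingConfig,
    amse,
    backprop_gradient,
    forward,
    init_weights,
    predict,
    select_learning_rate,
    train,
)


def flat(w: NetworkWeights) -> np.ndarray:
    return np.concatenate([w.w1.ravel(), w.a, w.w2, [w.b]])


def unflat(vec: np.ndarray, arch: Architecture) -> NetworkWeights:
    s, p = arch.n_hidden, arch.n_inputs
    w1 = vec[: s * p].reshape(s, p)
    a = vec[s * p : s * p + s]
    w2 = vec[s * p + s : s * p + 2 * s]
    return NetworkWeights(w1=w1, a=a, w2=w2, b=float(vec[-1]))


def objective(vec, arch, X, y, lam):
    w = unflat(vec, arch)
    return amse(predict(w, arch, X), y) + lam * (np.sum(w.w1**2) + np.sum(w.w2**2))


class TestInit:
    def test_range_and_determinism(self):
        arch = Architecture(n_inputs=4, n_hidden=3)
        cfg = TrainingConfig(seed=5)
        w = init_weights(arch, cfg)
        assert np.abs(flat(w)).max() <= 0.1
        np.testing.assert_array_equal(flat(w), flat(init_weights(arch, cfg)))

    def test_seeds_differ(self):
        arch = Architecture(n_inputs=4, n_hidden=3)
        w1 = init_weights(arch, TrainingConfig(seed=1))
        w2 = init_weights(arch, TrainingConfig(seed=2))
        assert not np.array_equal(flat(w1), flat(w2))


class TestForward:
    def test_zero_network_outputs_bias(self):
        arch = Architecture(n_inputs=3, n_hidden=2)
        w = NetworkWeights(w1=np.zeros((2, 3)), a=np.zeros(2), w2=np.zeros(2), b=0.3)
        assert forward(w, arch, np.array([5.0, -2.0, 7.0])) == pytest.approx(0.3)

    def test_linear_reduction(self):
        arch = Architecture(n_inputs=2, n_hidden=1, hidden_activation="identity")
        w = NetworkWeights(w1=np.array([[2.0, -1.0]]), a=np.zeros(1), w2=np.ones(1), b=0.0)
        x = np.array([3.0, 4.0])
        assert forward(w, arch, x) == pytest.approx(2 * 3 - 4)

    def test_tanh_hand_value(self):
        arch = Architecture(n_inputs=2, n_hidden=1, hidden_activation="tanh")
        w = NetworkWeights(w1=np.array([[1.0, 1.0]]), a=np.zeros(1), w2=np.ones(1), b=0.0)
        assert forward(w, arch, np.array([1.0, 0.0])) == pytest.approx(np.tanh(1.0), abs=1e-5)

    def test_shape_mismatch(self):
        arch = Architecture(n_inputs=3, n_hidden=1)
        w = init_weights(arch, TrainingConfig())
        with pytest.raises(ValidationError):
            forward(w, arch, np.zeros(4))

    def test_tanh_hidden_activations_bounded(self):
        arch = Architecture(n_inputs=5, n_hidden=4, hidden_activation="tanh")
        # covariates on the working scale [-1, 1], default small init
        w = init_weights(arch, TrainingConfig(seed=0))
        X = np.random.default_rng(0).uniform(-1, 1, size=(20, 5))
        Z = np.tanh(X @ w.w1.T + w.a)
        assert (np.abs(Z) < 1).all()


class TestAmse:
    def test_examples(self):
        assert amse(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0
        assert amse(np.array([0.0, 1.0]), np.array([1.0, 1.0])) == pytest.approx(0.5)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=10), rng.normal(size=10)
        perm = rng.permutation(10)
        assert amse(a, b) == pytest.approx(amse(a[perm], b[perm]))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            amse(np.zeros(3), np.zeros(4))


class TestGradient:
    def test_zero_at_perfect_fit_without_decay(self):
        arch = Architecture(n_inputs=2, n_hidden=1, hidden_activation="identity")
        w = NetworkWeights(w1=np.array([[1.0, 2.0]]), a=np.zeros(1), w2=np.ones(1), b=0.0)
        X = np.random.default_rng(1).normal(size=(6, 2))
        y = predict(w, arch, X)
        g = backprop_gradient(w, arch, X, y, weight_decay=0.0)
        np.testing.assert_allclose(flat(g), 0.0, atol=1e-12)

    def test_decay_gradient_vanishes_at_origin(self):
        arch = Architecture(n_inputs=3, n_hidden=2)
        w = NetworkWeights(w1=np.zeros((2, 3)), a=np.zeros(2), w2=np.zeros(2), b=0.0)
        X = np.random.default_rng(1).normal(size=(4, 3))
        y = np.zeros(4)
        g0 = backprop_gradient(w, arch, X, y, weight_decay=0.0)
        g1 = backprop_gradient(w, arch, X, y, weight_decay=0.5)
        np.testing.assert_allclose(flat(g0), flat(g1), atol=1e-14)

    @pytest.mark.parametrize("activation", ["tanh", "identity"])
    @pytest.mark.parametrize("lam", [0.0, 0.01])
    def test_matches_central_finite_differences(self, activation, lam):
        arch = Architecture(n_inputs=5, n_hidden=3, hidden_activation=activation)
        rng = np.random.default_rng(7)
        w = NetworkWeights(
            w1=rng.normal(scale=0.5, size=(3, 5)),
            a=rng.normal(scale=0.5, size=3),
            w2=rng.normal(scale=0.5, size=3),
            b=float(rng.normal()),
        )
        X = rng.normal(size=(7, 5))
        y = rng.normal(size=7)
        analytic = flat(backprop_gradient(w, arch, X, y, lam))
        vec = flat(w)
        h = 1e-6
        numeric = np.empty_like(vec)
        for i in range(len(vec)):
            up, dn = vec.copy(), vec.copy()
            up[i] += h
            dn[i] -= h
            numeric[i] = (objective(up, arch, X, y, lam) - objective(dn, arch, X, y, lam)) / (2 * h)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-6, atol=1e-9)


class TestTrain:
    def test_zero_iterations_returns_initial_weights(self):
        arch = Architecture(n_inputs=2, n_hidden=1)
        cfg = TrainingConfig(max_iterations=0, seed=3)
        X = np.random.default_rng(0).normal(size=(5, 2))
        trace = train(arch, cfg, X, np.zeros(5))
        assert trace.amse_per_iteration == []
        assert trace.stop_reason == "max_iterations"
        np.testing.assert_array_equal(flat(trace.final_weights), flat(init_weights(arch, cfg)))

    def test_converges_on_noiseless_linear_target(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        beta = np.array([0.3, -0.2, 0.1])
        y = X @ beta
        arch = Architecture(n_inputs=3, n_hidden=1, hidden_activation="identity")
        cfg = TrainingConfig(learning_rate=0.05, weight_decay=0.0, seed=1)
        trace = train(arch, cfg, X, y)
        assert trace.stop_reason == "amse_threshold"
        assert len(trace.amse_per_iteration) < 1000
        assert trace.amse_per_iteration[-1] <= 1e-3

    def test_descent_property_without_momentum(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        y = X @ rng.normal(size=4)
        arch = Architecture(n_inputs=4, n_hidden=1, hidden_activation="identity")
        cfg = TrainingConfig(
            learning_rate=0.01, momentum=0.0, weight_decay=0.0,
            max_iterations=200, amse_tolerance=1e-12, seed=2,
        )
        trace = train(arch, cfg, X, y)
        diffs = np.diff(trace.amse_per_iteration)
        assert (diffs <= 1e-12).all()

    def test_divergence_raises_with_iteration(self):
        rng = np.random.default_rng(6)
        X = rng.normal(scale=10, size=(20, 5))
        y = rng.normal(size=20)
        arch = Architecture(n_inputs=5, n_hidden=2, hidden_activation="identity")
        cfg = TrainingConfig(learning_rate=10.0, seed=1)
        with pytest.raises(TrainingDivergedError, match="iteration"):
            train(arch, cfg, X, y)

    def test_trajectory_invariant_to_sample_order(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        arch = Architecture(n_inputs=3, n_hidden=2)
        cfg = TrainingConfig(max_iterations=50, seed=9)
        perm = rng.permutation(25)
        t1 = train(arch, cfg, X, y)
        t2 = train(arch, cfg, X[perm], y[perm])
        np.testing.assert_allclose(
            t1.amse_per_iteration, t2.amse_per_iteration, rtol=1e-12
        )
        np.testing.assert_allclose(flat(t1.final_weights), flat(t2.final_weights), atol=1e-12)


class TestLinearNetworkClass:
    def test_identity_network_has_explicit_affine_form(self):
        # any identity-activation net equals the affine map with
        # coefficients w1.T @ w2 and intercept b + w2 . a
        arch = Architecture(n_inputs=6, n_hidden=4, hidden_activation="identity")
        w = init_weights(arch, TrainingConfig(seed=12, init_range=(-1, 1)))
        X = np.random.default_rng(13).normal(size=(15, 6))
        coef = w.w1.T @ w.w2
        intercept = w.b + w.w2 @ w.a
        np.testing.assert_allclose(predict(w, arch, X), X @ coef + intercept, atol=1e-10)


def test_select_learning_rate_rejects_divergent_candidates():
    rng = np.random.default_rng(10)
    X = rng.normal(scale=5, size=(30, 4))
    y = X @ rng.normal(size=4)
    arch = Architecture(n_inputs=4, n_hidden=1, hidden_activation="identity")
    cfg = TrainingConfig(seed=3, max_iterations=300)
    lr = select_learning_rate(arch, cfg, X, y, candidates=(10.0, 0.01, 0.001))
    assert lr in (0.01, 0.001)
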