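import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sterolkin as sk
from sterolkin.ann import (
    MLP_ACTIVATIONS,
    NetworkSpec,
    TrainedNetwork,
    activation,
    mlp_grid,
    rbf_grid,
)
from sterolkin.exceptions import DataError


def toy_problem(n=150, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform([0.75, 12, 0], [0.90, 30, 72], size=(n, 3))
    y = 8.0 - 0.02 * x[:, 2] + 2.0 * (x[:, 0] - 0.8) - 0.05 * (x[:, 1] - 20)
    return x, y + rng.normal(0, 0.05, n)


class TestActivation:
    def test_logistic_at_zero(self):
        assert activation("logistic", 0.0) == 0.5

    def test_tanh_and_gaussian_at_zero(self):
        assert activation("tanh", 0.0) == 0.0
        assert activation("gaussian", 0.0) == 1.0

    def test_exponential_is_exp(self):
        assert activation("exponential", 1.0) == pytest.approx(np.e)

    @given(st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_linear_identity(self, x):
        assert activation("linear", x) == x

    @given(st.floats(-30, 30))
    @settings(max_examples=50, deadline=None)
    def test_logistic_bounded(self, x):
        assert 0.0 < activation("logistic", x) < 1.0

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            activation("relu", 1.0)


class TestSpecAndSizing:
    def test_count_parameters_3_9_1(self):
        assert sk.count_parameters(NetworkSpec("mlp", 9)) == 46

    def test_count_parameters_3_1_1(self):
        assert sk.count_parameters(NetworkSpec("mlp", 1)) == 6

    def test_count_parameters_3_16_1(self):
        assert sk.count_parameters(NetworkSpec("mlp", 16)) == 81

    def test_hidden_rule_243(self):
        assert sk.estimate_hidden_nodes(243, 3, 1) == pytest.approx(9.52)

    def test_hidden_rule_minimum(self):
        assert sk.estimate_hidden_nodes(30, 3, 1) == 1.0

    @given(st.integers(1, 60))
    @settings(max_examples=30, deadline=None)
    def test_rule_inverts_parameter_count(self, h):
        # five cases per parameter: L = 5 * count_parameters recovers H exactly
        L = 5 * sk.count_parameters(NetworkSpec("mlp", h))
        assert sk.estimate_hidden_nodes(L, 3, 1) == pytest.approx(h)

    def test_rule_rejects_tiny_l(self):
        with pytest.raises(ValueError):
            sk.estimate_hidden_nodes(5, 3, 1)

    def test_rbf_requires_gaussian(self):
        with pytest.raises(ValueError):
            NetworkSpec("rbf", 3, "logistic")

    def test_mlp_rejects_gaussian(self):
        with pytest.raises(ValueError):
            NetworkSpec("mlp", 3, "gaussian")


def identity_scaled_net(spec, **params):
    """A network whose scaling is the identity on [0,1] inputs/targets."""
    defaults = dict(
        x_min=np.zeros(3),
        x_max=np.ones(3),
        y_min=0.0,
        y_max=1.0,
        init_seed=0,
    )
    defaults.update(params)
    return TrainedNetwork(spec=spec, **defaults)


class TestForward:
    def test_zero_weights_constant_output(self):
        net = identity_scaled_net(
            NetworkSpec("mlp", 4, "logistic"),
            hidden_weights=np.zeros((3, 4)),
            hidden_biases=np.zeros(4),
            output_weights=np.zeros(4),
            output_bias=0.3,
            y_min=2.0,
            y_max=6.0,
        )
        x = np.array([[0.1, 0.5, 0.9], [0.7, 0.2, 0.4]])
        # unscale(0.3) = 0.3 * 4 + 2
        np.testing.assert_allclose(net.predict(x), 3.2)

    def test_hand_computed_composition(self):
        w1 = np.array([[0.4], [-0.3], [0.2]])
        b1, w2, b2 = 0.1, 1.5, -0.2
        net = identity_scaled_net(
            NetworkSpec("mlp", 1, "logistic"),
            hidden_weights=w1,
            hidden_biases=np.array([b1]),
            output_weights=np.array([w2]),
            output_bias=b2,
            y_min=1.0,
            y_max=3.0,
        )
        x = np.array([[0.2, 0.8, 0.5]])
        z = 0.4 * 0.2 - 0.3 * 0.8 + 0.2 * 0.5 + b1
        expected = (w2 / (1 + np.exp(-z)) + b2) * 2.0 + 1.0
        np.testing.assert_allclose(net.predict(x), expected, rtol=1e-12)

    def test_rbf_node_at_input_activates_to_one(self):
        x = np.array([[0.3, 0.6, 0.2]])
        net = identity_scaled_net(
            NetworkSpec("rbf", 1, "gaussian"),
            centers=x.copy(),
            widths=np.array([0.37]),
            output_weights=np.array([1.0]),
            output_bias=0.0,
        )
        np.testing.assert_allclose(net.predict(x), 1.0)

    def test_extrapolation_flag(self):
        x, y = toy_problem()
        net = sk.train_mlp(NetworkSpec("mlp", 2), x, y, init_seed=0, max_iterations=5)
        inside = x[:1]
        outside = np.array([[0.95, 40.0, 100.0]])
        _, f_in = net.predict(inside, return_flags=True)
        _, f_out = net.predict(outside, return_flags=True)
        assert not f_in[0] and f_out[0]

    def test_forward_alias(self):
        x, y = toy_problem()
        net = sk.train_mlp(NetworkSpec("mlp", 2), x, y, init_seed=0, max_iterations=5)
        np.testing.assert_array_equal(sk.forward(net, x[:5]), net.predict(x[:5]))


class TestTrainMLP:
    def test_linear_data_exact(self):
        rng = np.random.default_rng(3)
        x = rng.uniform([0.75, 12, 0], [0.90, 30, 72], size=(100, 3))
        y = 1.0 + 2.0 * x[:, 0] - 0.1 * x[:, 1] + 0.03 * x[:, 2]
        net = sk.train_mlp(NetworkSpec("mlp", 3, "linear"), x, y, init_seed=0, max_iterations=300)
        assert net.errors["learning"] < 1e-6

    def test_zero_iterations_returns_initial(self):
        x, y = toy_problem()
        net = sk.train_mlp(NetworkSpec("mlp", 4), x, y, init_seed=5, max_iterations=0)
        rng = np.random.default_rng(5)
        theta0 = rng.uniform(-0.5, 0.5, size=sk.count_parameters(net.spec))
        np.testing.assert_array_equal(net.hidden_weights.ravel(), theta0[:12])
        assert net.errors["learning"] == net.mse(x, y)

    def test_deterministic(self):
        x, y = toy_problem()
        a = sk.train_mlp(NetworkSpec("mlp", 3), x, y, x[:30], y[:30], init_seed=7, max_iterations=50)
        b = sk.train_mlp(NetworkSpec("mlp", 3), x, y, x[:30], y[:30], init_seed=7, max_iterations=50)
        np.testing.assert_array_equal(a.hidden_weights, b.hidden_weights)
        np.testing.assert_array_equal(a.output_weights, b.output_weights)
        assert a.errors == b.errors

    def test_early_stopping_snapshot_not_worse_than_initial(self):
        x, y = toy_problem(seed=1)
        xt, yt = toy_problem(seed=2)
        spec = NetworkSpec("mlp", 6)
        trained = sk.train_mlp(spec, x, y, xt, yt, init_seed=1, max_iterations=100)
        initial = sk.train_mlp(spec, x, y, xt, yt, init_seed=1, max_iterations=0)
        assert trained.errors["test"] <= initial.errors["test"]

    @pytest.mark.parametrize("act", MLP_ACTIVATIONS)
    def test_all_activations_train(self, act):
        x, y = toy_problem()
        net = sk.train_mlp(NetworkSpec("mlp", 3, act), x, y, init_seed=0, max_iterations=40)
        assert np.isfinite(net.errors["learning"])

    def test_rejects_rbf_spec(self):
        x, y = toy_problem()
        with pytest.raises(ValueError):
            sk.train_mlp(NetworkSpec("rbf", 3, "gaussian"), x, y)


class TestTrainRBF:
    def test_constant_target(self):
        rng = np.random.default_rng(0)
        x = rng.uniform([0.75, 12, 0], [0.90, 30, 72], size=(60, 3))
        net = sk.train_rbf(NetworkSpec("rbf", 5, "gaussian"), x, np.full(60, 4.0), init_seed=0)
        assert net.errors["learning"] < 1e-12

    def test_interpolation_regime(self):
        rng = np.random.default_rng(4)
        x = rng.uniform([0.75, 12, 0], [0.90, 30, 72], size=(25, 3))
        y = rng.uniform(5, 9, 25)
        net = sk.train_rbf(
            NetworkSpec("rbf", 25, "gaussian"), x, y, init_seed=0, width_scale=0.05
        )
        assert net.errors["learning"] < 1e-8

    def test_deterministic(self):
        x, y = toy_problem()
        a = sk.train_rbf(NetworkSpec("rbf", 6, "gaussian"), x, y, init_seed=2)
        b = sk.train_rbf(NetworkSpec("rbf", 6, "gaussian"), x, y, init_seed=2)
        np.testing.assert_array_equal(a.centers, b.centers)
        np.testing.assert_array_equal(a.output_weights, b.output_weights)

    def test_too_many_hidden_nodes(self):
        x, y = toy_problem(n=10)
        with pytest.raises(DataError):
            sk.train_rbf(NetworkSpec("rbf", 11, "gaussian"), x, y)


class TestArchitectureSearch:
    def test_selection_weights_are_shares(self, split_dataset):
        result = sk.architecture_search(
            split_dataset, [NetworkSpec("mlp", 2)], restarts=1, base_seed=0, max_iterations=5
        )
        np.testing.assert_allclose(result.weights, (243 / 468, 108 / 468, 117 / 468))
        assert sum(result.weights) == pytest.approx(1.0)

    def test_single_topology(self, split_dataset):
        result = sk.architecture_search(
            split_dataset, [NetworkSpec("mlp", 3, "tanh")], restarts=2, base_seed=0, max_iterations=5
        )
        assert result.best.spec == NetworkSpec("mlp", 3, "tanh")

    def test_best_minimises_weighted_error(self, split_dataset):
        grid = [NetworkSpec("mlp", h) for h in (2, 3)]
        restarts, base_seed, max_iter = 2, 11, 10
        result = sk.architecture_search(
            split_dataset, grid, restarts=restarts, base_seed=base_seed, max_iterations=max_iter
        )
        # independent re-run of every training with the documented seed rule
        x_l, y_l = split_dataset.arrays(["learning"])
        x_t, y_t = split_dataset.arrays(["test"])
        x_v, y_v = split_dataset.arrays(["validation"])
        weighted = []
        for ti, spec in enumerate(grid):
            for r in range(restarts):
                net = sk.train_mlp(
                    spec, x_l, y_l, x_t, y_t,
                    init_seed=base_seed + ti * restarts + r, max_iterations=max_iter,
                )
                net.errors["validation"] = net.mse(x_v, y_v)
                weighted.append(net.weighted_error(result.weights))
        assert result.best_weighted_error == pytest.approx(min(weighted), rel=1e-12)

    def test_min_error_monotone_in_restarts(self, split_dataset):
        grid = [NetworkSpec("mlp", 3)]
        best = [
            sk.architecture_search(
                split_dataset, grid, restarts=r, base_seed=0, max_iterations=10
            ).best_weighted_error
            for r in (1, 2, 4)
        ]
        assert best[0] >= best[1] >= best[2]

    def test_weighted_error_of_uniform_errors(self):
        net = identity_scaled_net(
            NetworkSpec("mlp", 1),
            hidden_weights=np.zeros((3, 1)),
            hidden_biases=np.zeros(1),
            output_weights=np.zeros(1),
            output_bias=0.0,
        )
        net.errors = {"learning": 0.25, "test": 0.25, "validation": 0.25}
        assert net.weighted_error((0.52, 0.23, 0.25)) == pytest.approx(0.25)

    def test_empty_grid(self, split_dataset):
        with pytest.raises(ValueError):
            sk.architecture_search(split_dataset, [], restarts=1)

    def test_unsplit_dataset_rejected(self, paper_count_dataset):
        with pytest.raises(DataError):
            sk.architecture_search(paper_count_dataset, [NetworkSpec("mlp", 2)], restarts=1)

    def test_curves_shape(self, split_dataset):
        grid = mlp_grid([2, 3], ["logistic"]) + rbf_grid([2, 4])
        result = sk.architecture_search(
            split_dataset, grid, restarts=2, base_seed=0, max_iterations=5
        )
        assert len(result.curves) == 4
        assert set(result.curves.network_type) == {"mlp", "rbf"}
        assert result.curves.mean_learning_error.notna().all()


class TestSerialisation:
    @pytest.mark.parametrize("kind", ["mlp", "rbf"])
    def test_json_round_trip_bit_exact(self, kind, tmp_path):
        x, y = toy_problem()
        if kind == "mlp":
            net = sk.train_mlp(NetworkSpec("mlp", 3), x, y, x[:20], y[:20], init_seed=0, max_iterations=20)
        else:
            net = sk.train_rbf(NetworkSpec("rbf", 4, "gaussian"), x, y, init_seed=0)
        path = tmp_path / "net.json"
        net.save_json(path)
        loaded = TrainedNetwork.load_json(path)
        np.testing.assert_array_equal(loaded.predict(x), net.predict(x))
        assert loaded.spec == net.spec
        assert loaded.errors == net.errors
        # second save is byte-identical
        path2 = tmp_path / "net2.json"
        loaded.save_json(path2)
        assert path.read_bytes() == path2.read_bytes()
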