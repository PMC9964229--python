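"""GA-BP model: scaling, forward pass, GA pre-optimization, BP training,
the convergence rule, and one-at-a-time sensitivity analysis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from climflav.gabp import (
    BPConfig,
    GAConfig,
    NetworkConfig,
    bp_train,
    check_convergence,
    fit_gabp,
    flatten_weights,
    forward,
    ga_optimize,
    init_weights,
    n_parameters,
    scale_minmax,
    sensitivity,
    unflatten_weights,
)
from climflav.synthetic import CLIMATE_FACTORS, EffectSpec, gen_climate, gen_response


def _toy_config(layers, seed=0, **bp_kw):
    return NetworkConfig(
        layer_sizes=list(layers),
        ga=GAConfig(population=10, generations=5),
        bp=BPConfig(**bp_kw) if bp_kw else BPConfig(),
        seed=seed,
    )


class TestScaleMinmax:
    def test_maps_range_onto_bounds(self):
        Xs, params = scale_minmax(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(Xs[:, 0], [0.10, 0.50, 0.90])

    def test_constant_feature_midpoint_with_flag(self):
        with pytest.warns(UserWarning, match="constant"):
            Xs, params = scale_minmax(np.array([[5.0], [5.0], [5.0]]))
        assert np.allclose(Xs, 0.5)
        assert params.constant_mask[0]

    def test_round_trip_inverse(self, rng):
        X = rng.normal(size=(20, 5)) * rng.uniform(0.1, 100, 5)
        Xs, params = scale_minmax(X)
        assert np.allclose(params.inverse(Xs), X, atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            scale_minmax(np.array([[1.0, 2.0]]))


class TestForward:
    def test_zero_network_outputs_half(self):
        w = unflatten_weights(np.zeros(n_parameters([3, 4, 1])), [3, 4, 1])
        assert forward(w, np.zeros(3))[0] == 0.5

    def test_toy_net_hand_evaluation(self):
        # 1-1-1 net, unit weights, zero bias, input 0: sigma(sigma(0)*1) = sigma(0.5)
        w = unflatten_weights(np.array([1.0, 0.0, 1.0, 0.0]), [1, 1, 1])
        assert forward(w, np.array([0.0]))[0] == pytest.approx(
            1 / (1 + np.exp(-0.5))
        )

    @given(st.integers(0, 2**31 - 1))
    def test_output_strictly_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        w = unflatten_weights(rng.normal(0, 3, n_parameters([4, 6, 1])), [4, 6, 1])
        y = forward(w, rng.uniform(0.1, 0.9, (5, 4)))
        assert np.all((y > 0) & (y < 1))

    def test_dimension_mismatch_rejected(self):
        w = unflatten_weights(np.zeros(n_parameters([3, 2, 1])), [3, 2, 1])
        with pytest.raises(ValueError, match="features"):
            forward(w, np.zeros(4))

    def test_flatten_round_trip(self, rng):
        vec = rng.normal(size=n_parameters([8, 50, 30, 1]))
        assert np.array_equal(
            flatten_weights(unflatten_weights(vec, [8, 50, 30, 1])), vec
        )


class TestCheckConvergence:
    def test_boundary_is_strict(self):
        errors = np.full(10, 0.02)
        assert not check_convergence(errors, delta=0.02, n=10)

    def test_zero_errors_converged(self):
        assert check_convergence(np.zeros(5), delta=0.02, n=5)

    def test_hand_arithmetic_case(self):
        errors = np.full(10, 0.01)  # SSE 0.001 < 0.004, MAE 0.01 < 0.02
        assert check_convergence(errors, delta=0.02, n=10)

    def test_empty_errors_rejected(self):
        with pytest.raises(ValueError):
            check_convergence(np.array([]), delta=0.02, n=0)


class TestGaOptimize:
    def test_best_fitness_trace_nondecreasing(self):
        X = np.array([[0.1, 0.9], [0.9, 0.1], [0.5, 0.5]])
        y = np.array([0.2, 0.8, 0.5])
        for seed in range(5):
            cfg = _toy_config([2, 3, 1], seed=seed)
            res = ga_optimize(X, y, cfg)
            assert all(b >= a for a, b in zip(res.fitness_trace, res.fitness_trace[1:]))

    def test_zero_generations_returns_best_of_initial_population(self):
        X = np.array([[0.5], [0.7]])
        y = np.array([0.3, 0.6])
        cfg = NetworkConfig(layer_sizes=[1, 2, 1],
                            ga=GAConfig(population=8, generations=0), seed=4)
        res = ga_optimize(X, y, cfg)
        assert len(res.fitness_trace) == 1
        assert res.best_sse == pytest.approx(1.0 / res.fitness_trace[0] - 1.0)

    def test_ga_beats_random_initialization(self):
        # median paired improvement over 20 seeds on a reachable target
        X = np.array([[0.3, 0.7]])
        y = np.array([0.8])
        diffs = []
        for seed in range(20):
            cfg = NetworkConfig(layer_sizes=[2, 3, 1],
                                ga=GAConfig(population=20, generations=30), seed=seed)
            rng = np.random.default_rng(seed)
            rand = init_weights(cfg.layer_sizes, rng, cfg.ga.init_scale)
            sse_rand = float(np.sum(
                (forward(unflatten_weights(rand, cfg.layer_sizes), X) - y) ** 2))
            res = ga_optimize(X, y, cfg)
            diffs.append(sse_rand - res.best_sse)
        assert np.median(diffs) > 0

    def test_tiny_population_rejected(self):
        cfg = NetworkConfig(layer_sizes=[2, 2, 1], ga=GAConfig(population=1))
        with pytest.raises(ValueError):
            ga_optimize(np.array([[0.5, 0.5]]), np.array([0.5]), cfg)

    def test_seeded_determinism(self):
        X = np.array([[0.2, 0.4], [0.6, 0.8]])
        y = np.array([0.3, 0.7])
        cfg = _toy_config([2, 3, 1], seed=11)
        a = ga_optimize(X, y, cfg)
        b = ga_optimize(X, y, _toy_config([2, 3, 1], seed=11))
        assert np.array_equal(a.best_vector, b.best_vector)


class TestBpTrain:
    def test_zero_learning_rate_leaves_weights_unchanged(self):
        X = np.array([[0.2, 0.8], [0.8, 0.2]])
        y = np.array([0.2, 0.8])
        cfg = _toy_config([2, 3, 1], learning_rate=0.0, max_epochs=50)
        vec = init_weights(cfg.layer_sizes, np.random.default_rng(0))
        net = bp_train(vec, X, y, cfg)
        assert np.array_equal(flatten_weights(net.weights), vec)
        assert len(set(np.round(net.error_trace, 15))) == 1

    def test_xor_learned_by_small_net(self):
        X = np.array([[0.1, 0.1], [0.1, 0.9], [0.9, 0.1], [0.9, 0.9]])
        y = np.array([0.1, 0.9, 0.9, 0.1])
        wins = 0
        for seed in range(10):
            cfg = NetworkConfig(layer_sizes=[2, 4, 1],
                                ga=GAConfig(population=30, generations=40),
                                seed=seed)
            res = ga_optimize(X, y, cfg)
            net = bp_train(res.best_vector, X, y, cfg)
            mae = float(np.mean(np.abs(forward(net.weights, X) - y)))
            wins += mae < 0.02
        assert wins >= 8

    def test_bp_starts_from_ga_solution(self):
        X = np.array([[0.2, 0.5], [0.7, 0.3], [0.4, 0.9]])
        y = np.array([0.4, 0.6, 0.5])
        cfg = _toy_config([2, 3, 1], seed=2)
        res = ga_optimize(X, y, cfg)
        net = bp_train(res.best_vector, X, y, cfg)
        assert net.error_trace[0] == pytest.approx(res.best_sse)
        assert net.error_trace[-1] <= res.best_sse + 1e-12


class TestSensitivity:
    def _train_linear(self, coeffs, n, seed, layers=(8, 20, 10, 1)):
        clim = gen_climate(n, seed=seed)
        draw = gen_response(clim, EffectSpec(coefficients=coeffs, noise_sd=0.02),
                            seed=seed + 99)
        cfg = NetworkConfig(layer_sizes=list(layers),
                            ga=GAConfig(population=20, generations=20),
                            bp=BPConfig(max_epochs=1500), seed=seed)
        X = clim[list(CLIMATE_FACTORS)].to_numpy()
        net = fit_gabp(X, draw.values.to_numpy(), cfg)
        return net, net.x_scaler.transform(X)

    def test_dead_input_has_zero_sensitivity(self):
        vec = np.random.default_rng(0).normal(0, 0.5, n_parameters([3, 4, 1]))
        w = unflatten_weights(vec, [3, 4, 1])
        w[0][0][2, :] = 0.0  # sever all first-layer weights from input 2
        net_cfg = NetworkConfig(layer_sizes=[3, 4, 1])
        from climflav.gabp import TrainedNetwork

        net = TrainedNetwork(weights=w, config=net_cfg)
        prof = sensitivity(net, np.random.default_rng(1).uniform(0.1, 0.9, (10, 3)))
        assert prof.values[2] == 0.0
        assert prof.values.sum() == pytest.approx(1.0)

    def test_planted_dominant_factor_ranked_first(self):
        net, Xs = self._train_linear(
            {"MIT": 2.0, "AT": 0.3, "SD": -0.3, "DP": 0.2}, n=100, seed=5
        )
        prof = sensitivity(net, Xs, factors=list(CLIMATE_FACTORS))
        assert prof.top_factor() == "MIT"

    def test_coefficient_ratio_recovered(self):
        # linear response with 1:2 coefficients on two z-scored factors;
        # ARH and SD are generated independently, so no cross-factor leakage
        net, Xs = self._train_linear({"ARH": 1.0, "SD": 2.0}, n=200, seed=8)
        prof = sensitivity(net, Xs, factors=list(CLIMATE_FACTORS))
        s = dict(zip(prof.factors, prof.values))
        assert 1.5 <= s["SD"] / s["ARH"] <= 2.5

    def test_permutation_equivariance(self):
        vec = np.random.default_rng(3).normal(0, 0.5, n_parameters([4, 5, 1]))
        w = unflatten_weights(vec, [4, 5, 1])
        from climflav.gabp import TrainedNetwork

        cfg = NetworkConfig(layer_sizes=[4, 5, 1])
        X = np.random.default_rng(4).uniform(0.1, 0.9, (15, 4))
        base = sensitivity(TrainedNetwork(weights=w, config=cfg), X)
        perm = [2, 0, 3, 1]
        w2 = [(w[0][0][perm, :].copy(), w[0][1].copy())] + [
            (W.copy(), b.copy()) for W, b in w[1:]
        ]
        permuted = sensitivity(TrainedNetwork(weights=w2, config=cfg), X[:, perm])
        # input j of the permuted net is original input perm[j]
        assert np.allclose(permuted.values, base.values[perm], atol=1e-9)

    def test_nonpositive_perturbation_rejected(self):
        from climflav.gabp import TrainedNetwork

        w = unflatten_weights(np.zeros(n_parameters([2, 2, 1])), [2, 2, 1])
        net = TrainedNetwork(weights=w, config=NetworkConfig(layer_sizes=[2, 2, 1]))
        with pytest.raises(ValueError):
            sensitivity(net, np.full((3, 2), 0.5), perturbation=0.0)


class TestFitGabp:
    def test_seeded_determinism_end_to_end(self):
        clim = gen_climate(25, seed=3)
        draw = gen_response(clim, EffectSpec(coefficients={"OP": 1.0}), seed=7)
        X = clim[list(CLIMATE_FACTORS)].to_numpy()
        cfg = dict(layer_sizes=[8, 10, 5, 1],
                   ga=dict(population=10, generations=10),
                   bp=dict(max_epochs=200), seed=21)
        a = fit_gabp(X, draw.values.to_numpy(), NetworkConfig.from_dict(cfg))
        b = fit_gabp(X, draw.values.to_numpy(), NetworkConfig.from_dict(cfg))
        assert np.array_equal(flatten_weights(a.weights), flatten_weights(b.weights))

    def test_small_sample_warning(self):
        clim = gen_climate(9, seed=1)
        draw = gen_response(clim, EffectSpec(coefficients={"AT": 1.0}), seed=1)
        cfg = NetworkConfig(layer_sizes=[8, 4, 1],
                            ga=GAConfig(population=6, generations=2),
                            bp=BPConfig(max_epochs=20), seed=0)
        with pytest.warns(UserWarning, match="training-set"):
            fit_gabp(clim[list(CLIMATE_FACTORS)].to_numpy(), draw.values.to_numpy(), cfg)
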