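"""Tests of encoding, GA search, analytic gradients and the hybrid trainer."""

import numpy as np
import pytest

from conftest import tiny_params
from fuzzywave import (
    GAConfig,
    GDConfig,
    baseline_nn_train,
    batch_predict,
    decode,
    encode,
    fitness,
    ga_optimize,
    gd_gradients,
    gd_train,
    hybrid_train,
    make_teacher_fwnn,
)
from fuzzywave.errors import ConfigError, SchemaError
from fuzzywave.fwnn import _aggregate, _layers
from fuzzywave.training import _mse_and_gradients, _numeric_gradients, chromosome_length


def _teacher_data(n_rules=2, n_inputs=2, n=200, seed=5, noise_sd=0.0):
    rng = np.random.default_rng(seed)
    teacher = make_teacher_fwnn(n_rules, n_inputs, seed=seed)
    X = rng.uniform(-1, 1, (n, n_inputs))
    y = batch_predict(teacher, X)
    if noise_sd:
        y = y + rng.normal(0, noise_sd, n)
    return X, y, teacher


class TestEncodeDecode:
    def test_layout_length(self):
        assert chromosome_length(2, 2) == 18
        p = tiny_params(2, 2)
        assert encode(p).shape == (18,)

    def test_round_trip_reference_bit_identical(self, reference_params):
        back = decode(encode(reference_params), 5, 8)
        for name in ("centers", "spreads", "dilations", "translations", "weights"):
            np.testing.assert_array_equal(getattr(back, name), getattr(reference_params, name))

    def test_decode_then_encode_identity(self, rng):
        chrom = rng.uniform(-2, 2, chromosome_length(3, 4))
        chrom[np.abs(chrom) < 1e-5] = 0.5  # keep away from the divisor clamp
        np.testing.assert_array_equal(encode(decode(chrom, 3, 4)), chrom)

    def test_decode_clamps_tiny_divisors(self):
        chrom = np.zeros(chromosome_length(1, 1) )
        p = decode(chrom, 1, 1)
        assert p.spreads[0, 0] == 1e-6 and p.dilations[0, 0] == 1e-6

    def test_wrong_length_rejected(self):
        with pytest.raises(SchemaError):
            decode(np.zeros(17), 2, 2)


class TestFitness:
    def test_perfect_predictor_scores_one(self):
        X, y, teacher = _teacher_data()
        assert fitness(encode(teacher), X, y, 2) == pytest.approx(1.0)

    def test_composes_predict_and_mse(self, rng):
        X, y, _ = _teacher_data()
        chrom = encode(tiny_params(2, 2, seed=3))
        pred = batch_predict(decode(chrom, 2, 2), X)
        mse = np.mean((pred - y) ** 2)
        assert fitness(chrom, X, y, 2) == pytest.approx(1.0 / (1.0 + mse), rel=1e-12)

    def test_known_mse_half(self):
        # a model predicting y+1 everywhere has MSE 1 -> fitness 0.5
        X, y, teacher = _teacher_data()
        chrom = encode(teacher)
        assert fitness(chrom, X, y - 1.0, 2) == pytest.approx(0.5, rel=1e-12)

    def test_degenerate_activation_scores_zero(self):
        p = tiny_params(2, 5)
        p.centers[:] = 500.0
        p.spreads[:] = 1e-3
        X = np.zeros((3, 5))
        assert fitness(encode(p), X, np.zeros(3), 2) == 0.0


class TestGA:
    def test_no_variation_keeps_best(self):
        X, y, _ = _teacher_data(n=30)
        cfg = GAConfig(population_size=10, crossover_rate=0.0, mutation_rate=0.0,
                       max_generations=15, seed=3)
        best, trace = ga_optimize(X, y, 2, cfg)
        assert trace[-1] == pytest.approx(trace[0])

    def test_elitism_trace_non_decreasing(self):
        X, y, _ = _teacher_data(n=40)
        cfg = GAConfig(population_size=16, max_generations=25, seed=11)
        _, trace = ga_optimize(X, y, 2, cfg)
        assert all(b >= a for a, b in zip(trace, trace[1:]))
        assert trace[-1] >= trace[0]

    def test_seed_determinism_bit_identical(self):
        X, y, _ = _teacher_data(n=40)
        cfg = GAConfig(population_size=12, max_generations=10, seed=42)
        b1, t1 = ga_optimize(X, y, 2, cfg)
        b2, t2 = ga_optimize(X, y, 2, GAConfig(population_size=12, max_generations=10, seed=42))
        np.testing.assert_array_equal(b1, b2)
        assert t1 == t2

    def test_tiny_population_rejected(self):
        X, y, _ = _teacher_data(n=10)
        with pytest.raises(ConfigError):
            ga_optimize(X, y, 2, GAConfig(population_size=1))


class TestGradients:
    def test_zero_residual_gives_zero_gradients(self):
        from fuzzywave import forward

        p = tiny_params(2, 3, seed=8)
        x = np.array([0.2, -0.1, 0.4])
        yhat, _ = forward(p, x)
        grads = gd_gradients(p, x, yhat)
        for g in grads.values():
            np.testing.assert_allclose(g, 0.0, atol=1e-14)

    def test_weight_gradient_closed_form_normalized(self):
        p = tiny_params(3, 2, seed=2)
        x = np.array([0.3, -0.6])
        y_target = 0.7
        F, mu, z, psi, psihat = _layers(p, x[None, :])
        Psi = psi.prod(axis=2)[0]
        S = mu[0].sum()
        yhat = _aggregate(mu, psihat, "normalized")[0]
        expected = 2 * (yhat - y_target) * mu[0] * Psi / S
        grads = gd_gradients(p, x, y_target, aggregation="normalized")
        np.testing.assert_allclose(grads["weights"], expected, rtol=1e-12)

    @pytest.mark.parametrize("aggregation", ["normalized", "sum"])
    def test_matches_central_finite_differences(self, aggregation):
        for seed in range(20):
            local = np.random.default_rng(seed)
            R, n = int(local.integers(1, 4)), int(local.integers(1, 4))
            p = tiny_params(R, n, seed=seed + 100)
            p.aggregation = aggregation
            X = local.uniform(-1, 1, (4, n))
            y = local.uniform(-1, 1, 4)
            mse, grads = _mse_and_gradients(p, X, y, aggregation)
            num = _numeric_gradients(p, X, y, aggregation)
            for name in grads:
                scale = np.maximum(np.abs(num[name]), 1e-3)
                assert np.max(np.abs(grads[name] - num[name]) / scale) < 1e-5, name


class TestGDTrain:
    def test_tiny_learning_rate_leaves_params_unchanged(self):
        p = tiny_params(2, 2, seed=4)
        X, y, _ = _teacher_data(n=30)
        out, trace = gd_train(p, X, y, GDConfig(learning_rate=1e-300, max_epochs=5, target_error=0.0))
        np.testing.assert_allclose(out.centers, p.centers, atol=1e-12)
        np.testing.assert_allclose(out.weights, p.weights, atol=1e-12)
        assert trace == pytest.approx([trace[0]] * len(trace))

    def test_weights_only_converges_to_least_squares(self):
        # with every group but w frozen the loss is quadratic in w
        p = tiny_params(3, 2, seed=9)
        X, y, _ = _teacher_data(n_rules=3, n=60, seed=9)
        F, mu, z, psi, psihat = _layers(p, X)
        Psi = psi.prod(axis=2)
        S = mu.sum(axis=1)
        design = mu * Psi / S[:, None]
        w_star, *_ = np.linalg.lstsq(design, y, rcond=None)
        lam = np.linalg.eigvalsh(2.0 * design.T @ design / X.shape[0]).max()
        cfg = GDConfig(learning_rate=0.9 / lam, max_epochs=4000, target_error=0.0)
        out, trace = gd_train(p, X, y, cfg, groups=("weights",))
        np.testing.assert_allclose(out.weights, w_star, atol=1e-4)

    def test_loss_trace_non_increasing_at_small_rate(self):
        X, y, _ = _teacher_data(n=80, seed=13)
        p = tiny_params(2, 2, seed=13)
        _, trace = gd_train(p, X, y, GDConfig(learning_rate=1e-3, max_epochs=50, target_error=0.0))
        assert all(b <= a + 1e-12 for a, b in zip(trace[:49], trace[1:50]))


class TestHybrid:
    def test_determinism_identical_reports(self):
        X, y, _ = _teacher_data(n=60)
        split = ((X[:40], y[:40]), (X[40:], y[40:]))
        kw = dict(
            n_rules=2,
            ga_config=GAConfig(population_size=10, max_generations=8, seed=21),
            gd_config=GDConfig(max_epochs=20),
        )
        r1 = hybrid_train(*split, **kw)
        kw["ga_config"] = GAConfig(population_size=10, max_generations=8, seed=21)
        r2 = hybrid_train(*split, **kw)
        np.testing.assert_array_equal(r1.final_params.weights, r2.final_params.weights)
        np.testing.assert_array_equal(r1.final_params.centers, r2.final_params.centers)
        assert r1.ga_best_fitness_per_generation == r2.ga_best_fitness_per_generation
        assert r1.gd_train_mse_per_epoch == r2.gd_train_mse_per_epoch
        assert r1.train_metrics.mse == r2.train_metrics.mse

    def test_gd_stage_does_not_worsen_at_small_rate(self):
        X, y, _ = _teacher_data(n=100, seed=17)
        split = ((X[:70], y[:70]), (X[70:], y[70:]))
        ga = GAConfig(population_size=16, max_generations=15, seed=17)
        best, _ = ga_optimize(X[:70], y[:70], 2, ga)
        mse_ga = np.mean((batch_predict(decode(best, 2, 2), X[:70]) - y[:70]) ** 2)
        report = hybrid_train(
            *split, n_rules=2,
            ga_config=GAConfig(population_size=16, max_generations=15, seed=17),
            gd_config=GDConfig(learning_rate=1e-3, max_epochs=100),
        )
        assert report.train_metrics.mse <= mse_ga + 1e-12


class TestHybridBeatsStages:
    def test_hybrid_at_least_as_good_as_either_stage_alone(self):
        """GA-then-GD should not lose to GA-only or GD-from-random at matched budgets."""
        from fuzzywave.training import InitRanges, _gene_bounds_fwnn

        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y, _ = _teacher_data(seed=seed)
            rep = hybrid_train(
                (X, y), None, n_rules=2,
                ga_config=GAConfig(population_size=20, max_generations=20, seed=seed),
                gd_config=GDConfig(max_epochs=100),
            )
            best, _ = ga_optimize(
                X, y, 2, GAConfig(population_size=20, max_generations=20, seed=seed)
            )
            mse_ga = np.mean((batch_predict(decode(best, 2, 2), X) - y) ** 2)
            low, high, signed = _gene_bounds_fwnn(2, 2, InitRanges())
            r2 = np.random.default_rng(seed)
            chrom = r2.uniform(low, high)
            chrom[signed] *= r2.choice([-1.0, 1.0], size=signed.sum())
            gd_only, _ = gd_train(decode(chrom, 2, 2), X, y, GDConfig(max_epochs=100))
            mse_gd = np.mean((batch_predict(gd_only, X) - y) ** 2)
            wins += rep.train_metrics.mse <= min(mse_ga, mse_gd) + 1e-15
        assert wins >= 8


class TestBaselineNN:
    def test_zero_hidden_units_matches_ols(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, (80, 3))
        beta = np.array([0.7, -0.4, 0.2])
        y = X @ beta + 0.05
        report = baseline_nn_train(
            ((X, y)), None, hidden_units=0,
            ga_config=GAConfig(population_size=10, max_generations=5, seed=1),
            gd_config=GDConfig(learning_rate=0.2, max_epochs=4000, target_error=0.0),
        )
        A = np.column_stack([X, np.ones(len(X))])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(report.final_params.output_weights, coef[:3], atol=1e-4)
        assert report.final_params.output_bias == pytest.approx(coef[3], abs=1e-4)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, (40, 2))
        y = np.tanh(X[:, 0]) - 0.3 * X[:, 1]
        kw = dict(hidden_units=3,
                  ga_config=GAConfig(population_size=10, max_generations=5, seed=8),
                  gd_config=GDConfig(max_epochs=30))
        r1 = baseline_nn_train((X, y), None, **kw)
        kw["ga_config"] = GAConfig(population_size=10, max_generations=5, seed=8)
        r2 = baseline_nn_train((X, y), None, **kw)
        np.testing.assert_array_equal(r1.final_params.output_weights, r2.final_params.output_weights)

    def test_linear_teacher_high_test_r2(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(-1, 1, (120, 2))
        y = 0.8 * X[:, 0] - 0.5 * X[:, 1] + 0.1
        report = baseline_nn_train(
            (X[:80], y[:80]), (X[80:], y[80:]), hidden_units=0,
            ga_config=GAConfig(population_size=10, max_generations=5, seed=2),
            gd_config=GDConfig(learning_rate=0.2, max_epochs=3000, target_error=1e-12),
        )
        assert report.test_metrics.r_squared > 0.99
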