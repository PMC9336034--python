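"""Forward pass, analytic gradients and the two training regimes."""

import dataclasses

import numpy as np
import pytest

from refmix.data import LabeledDataset
from refmix.network import (
    FitConfig,
    NetworkWeights,
    forward,
    glorot_uniform_init,
    nll_and_gradient,
    train_adam,
    train_bfgs,
)

from helpers import VARIANTS, random_instance, zero_weights


class TestForward:
    def test_zero_heads_give_uniform_weights_and_zero_means(self):
        surf = forward(zero_weights(), np.linspace(-1, 1, 7))
        np.testing.assert_allclose(surf.weights, 0.5)
        np.testing.assert_allclose(surf.means, 0.0)

    def test_zero_sigma_head_exponential_gives_unit_scale(self):
        surf = forward(zero_weights(scale_activation="exponential"), np.zeros(3))
        np.testing.assert_allclose(surf.scales, 1.0)

    def test_zero_sigma_head_softplus_gives_log_two(self):
        surf = forward(zero_weights(scale_activation="softplus"), np.zeros(3))
        np.testing.assert_allclose(surf.scales, np.log(2.0))

    def test_disconnected_alpha_constant_across_observations(self):
        w, data = random_instance(5, connected=False)
        surf = forward(w, data.covariate)
        assert np.ptp(surf.weights, axis=0).max() == 0.0

    def test_nonfinite_weights_rejected(self):
        w = zero_weights()
        bad = dataclasses.replace(w, mu_b=np.array([np.nan, 0.0]))
        with pytest.raises(ValueError):
            forward(bad, np.zeros(2))


class TestFlattening:
    @pytest.mark.parametrize("connected,activation", VARIANTS)
    def test_flatten_unflatten_roundtrip(self, connected, activation):
        w, _ = random_instance(2, connected=connected, activation=activation)
        theta = w.flatten()
        assert theta.shape == (w.n_params,)
        back = w.unflatten(theta)
        np.testing.assert_array_equal(back.flatten(), theta)

    def test_disconnected_alpha_matrix_not_trainable(self):
        full, _ = random_instance(3, connected=True)
        const, _ = random_instance(3, connected=False)
        assert const.n_params == full.n_params - const.alpha_w.size


class TestGradients:
    @pytest.mark.parametrize("connected,activation", VARIANTS)
    def test_matches_central_finite_differences(self, connected, activation):
        for seed in range(3):
            w, data = random_instance(
                10 + seed, connected=connected, activation=activation
            )
            nll, grad = nll_and_gradient(w, data)
            theta = w.flatten()
            step = 1e-6
            for j in range(theta.size):
                up, down = theta.copy(), theta.copy()
                up[j] += step
                down[j] -= step
                fd = (
                    nll_and_gradient(w.unflatten(up), data)[0]
                    - nll_and_gradient(w.unflatten(down), data)[0]
                ) / (2 * step)
                denom = max(1.0, abs(fd))
                assert abs(grad[j] - fd) / denom < 1e-5

    def test_alpha_bias_gradient_sums_to_zero(self):
        # softmax constraint: per-observation alpha pre-activation gradients
        # sum to zero, hence so does the alpha bias gradient block
        w, data = random_instance(7)
        _, grad = nll_and_gradient(w, data)
        h, m = w.n_hidden, w.n_components
        offset = w.hidden_w.size + w.hidden_b.size + w.alpha_w.size
        alpha_bias_grad = grad[offset : offset + m]
        assert alpha_bias_grad.sum() == pytest.approx(0.0, abs=1e-10)

    def test_single_component_mean_gradient_vanishes_at_sample_mean(self, rng):
        y = rng.normal(3.0, 1.0, 80)
        data = LabeledDataset(np.zeros(80), y)
        w = zero_weights(m=1)
        at_mean = dataclasses.replace(w, mu_b=np.array([y.mean()]))
        off_mean = dataclasses.replace(w, mu_b=np.array([y.mean() + 0.5]))
        mu_bias_index = w.hidden_w.size + w.hidden_b.size + w.alpha_w.size + 1 + w.mu_w.size
        assert nll_and_gradient(at_mean, data)[1][mu_bias_index] == pytest.approx(
            0.0, abs=1e-9
        )
        assert abs(nll_and_gradient(off_mean, data)[1][mu_bias_index]) > 1.0


class TestGlorotInit:
    def test_hidden_matrix_within_unit_bound(self):
        w = glorot_uniform_init(hidden_units=5, seed=0)
        assert np.all(np.abs(w.hidden_w) <= 1.0)  # sqrt(6/(1+5)) = 1
        assert np.all(w.hidden_b == 0)

    def test_reproducible_under_seed(self):
        a = glorot_uniform_init(seed=42)
        b = glorot_uniform_init(seed=42)
        np.testing.assert_array_equal(a.flatten(), b.flatten())

    def test_uniform_moments(self):
        draws = np.concatenate(
            [glorot_uniform_init(hidden_units=50, seed=s).hidden_w.ravel()
             for s in range(4)]
        )
        limit = np.sqrt(6.0 / 51.0)
        se = limit / np.sqrt(3.0) / np.sqrt(draws.size)
        assert abs(draws.mean()) < 3 * se


class TestTrainBfgs:
    def test_descent_from_random_init(self):
        w, data = random_instance(21, n=300)
        fitted = train_bfgs(data, w)
        nll0, _ = nll_and_gradient(w, data)
        assert fitted.loss <= nll0 + 1e-9

    def test_stationary_point_is_a_fixed_point(self, rng):
        # single-component Gaussian MLE: mu = sample mean, sigma = MLE sd,
        # all hidden-to-output weights zero -> exact stationary point
        y = rng.normal(2.0, 1.5, 200)
        data = LabeledDataset(rng.uniform(-1, 1, 200), y)
        w = zero_weights(m=1)
        w = dataclasses.replace(
            w,
            mu_b=np.array([y.mean()]),
            sigma_b=np.array([np.log(y.std())]),
        )
        fitted = train_bfgs(data, w)
        nll0, grad0 = nll_and_gradient(w, data)
        assert np.linalg.norm(grad0, np.inf) < 1e-8
        assert fitted.loss == pytest.approx(nll0, abs=1e-8)
        assert fitted.n_iter <= 1

    def test_refit_from_solution_does_not_regress(self):
        w, data = random_instance(22, n=300)
        first = train_bfgs(data, w)
        second = train_bfgs(data, first.weights_or_params)
        assert second.loss <= first.loss + 1e-9

    def test_nested_full_model_at_least_as_good_as_constant(self):
        wc, data = random_instance(23, n=400, connected=False)
        const_fit = train_bfgs(data, wc)
        relaxed = dataclasses.replace(
            const_fit.weights_or_params, alpha_connected=True
        )
        full_fit = train_bfgs(data, relaxed)
        assert full_fit.loss <= const_fit.loss + 1e-8

    def test_label_symmetry_of_permuted_init(self):
        w, data = random_instance(24, n=300)
        a = train_bfgs(data, w)
        b = train_bfgs(data, w.permuted([1, 0]))
        assert b.loss == pytest.approx(a.loss, rel=1e-3)


class TestTrainAdam:
    def test_zero_learning_rate_is_identity(self):
        w, data = random_instance(31, n=120)
        cfg = FitConfig(learning_rate=0.0, max_epochs=40, seed=0)
        fitted = train_adam(data, w, cfg)
        np.testing.assert_array_equal(
            fitted.weights_or_params.flatten(), w.flatten()
        )

    def test_early_stopping_rule(self):
        w, data = random_instance(32, n=400, activation="softplus")
        cfg = FitConfig(max_epochs=2000, patience=20, seed=1)
        fitted = train_adam(data, w, cfg)
        history = fitted.history["validation_nll"]
        running_best = np.minimum.accumulate(history)
        assert np.all(np.diff(running_best) <= 0)
        if fitted.converged:  # patience triggered
            best_epoch = int(np.argmin(history))
            assert fitted.n_iter == best_epoch + cfg.patience
            assert np.min(history) == fitted.history["best_validation"]

    def test_training_reduces_loss_on_easy_data(self):
        w, data = random_instance(33, n=500, activation="softplus")
        fitted = train_adam(data, w, FitConfig(max_epochs=300, seed=2))
        nll0, _ = nll_and_gradient(w, data)
        assert fitted.loss < nll0

    def test_too_small_sample_rejected(self):
        w, data = random_instance(34, n=8)
        with pytest.raises(ValueError):
            train_adam(data, w)
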