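"""STBP co-optimization: surrogate, gradients, protocol, reproducibility."""

import math

import numpy as np
import pytest

from cssnn import (
    CSSNN,
    TrainConfig,
    atan_surrogate,
    compute_gradients,
    compute_loss,
    evaluate_accuracy,
    fit,
    surrogate_atan_grad,
    sweep,
)
from cssnn.model import forward_batch
from cssnn.training import AdamW, train_step


class TestSurrogate:
    def test_peak_value_is_half_alpha(self):
        assert surrogate_atan_grad(0.0, alpha=2.0) == pytest.approx(1.0)
        assert surrogate_atan_grad(0.0, alpha=4.0) == pytest.approx(2.0)

    def test_symmetry(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(
            surrogate_atan_grad(x), surrogate_atan_grad(-x), rtol=1e-12
        )

    def test_closed_form_value(self):
        assert surrogate_atan_grad(1.0, alpha=2.0) == pytest.approx(
            1.0 / (1.0 + math.pi**2)
        )

    def test_is_derivative_of_smooth_spike(self):
        eps = 1e-6
        for x in (-1.2, -0.3, 0.0, 0.4, 2.0):
            fd = (atan_surrogate(x + eps) - atan_surrogate(x - eps)) / (2 * eps)
            assert fd == pytest.approx(surrogate_atan_grad(x), rel=1e-5)

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(ValueError):
            surrogate_atan_grad(0.0, alpha=0.0)


class TestForward:
    def test_full_sampling_is_unpruned_projection(self, rng):
        """Sample = n makes the mask all ones; the encoder current is then
        the plain row-sum of the input."""
        model = CSSNN.build("6-cs2-fc3-fc2", sample=6, T=2, seed=0)
        X = rng.uniform(0, 1, (3, 6))
        assert (model.encoder.binary() == 1).all()
        np.testing.assert_allclose(model.encoder_current(X), X.sum(axis=1)[:, None] @ np.ones((1, 2)))

    def test_frozen_weights_give_identical_outputs(self, rng):
        model = CSSNN.build("8-cs3-fc4-fc2", sample=2, T=4, seed=1)
        X = rng.uniform(0, 1, (2, 8))
        a = forward_batch(model, X)
        b = forward_batch(model, X)
        for sa, sb in zip(a.spikes, b.spikes):
            np.testing.assert_array_equal(sa, sb)

    def test_batched_forward_matches_reference_simulation(self, rng):
        """The vectorized training forward and the layered single-sample
        LIF simulation are the same dynamical system."""
        model = CSSNN.build("10-cs4-fc5-fc3", sample=3, T=6, seed=2)
        X = rng.uniform(0, 1, (4, 10))
        sim = forward_batch(model, X)
        for i in range(4):
            rasters = model.forward_sample(X[i])
            for layer, r in enumerate(rasters):
                np.testing.assert_array_equal(sim.spikes[layer][:, i, :], r.s)

    def test_hand_traced_two_step_forward(self):
        """4-cs2-fc3-fc2 with unit-sum weights, traced by explicit recursion."""
        model = CSSNN.build("4-cs2-fc3-fc2", sample=2, T=2, seed=0)
        model.encoder.W = np.array(
            [[0.9, 0.8, -0.5, -0.5], [-0.5, -0.5, 0.9, 0.8]]
        )
        model.weights = [np.full((3, 2), 0.6), np.full((2, 3), 0.4)]
        x = np.array([[0.5, 0.6, 0.0, 0.0]])
        sim = forward_batch(model, x, T=2)
        decay = model.lif.decay
        # encoder current: rows sample pixels {0,1} and {2,3} -> [1.1, 0.0]
        # t0: enc v=[1.1, 0] -> spike [1,0]; hidden c=0.6 each, v=0.6, no spike
        # t1: enc v=[1.1, 0] -> spike again; hidden v=0.6*decay+0.6=0.964 -> no
        assert list(sim.spikes[0][:, 0, 0]) == [1, 1]
        assert list(sim.spikes[0][:, 0, 1]) == [0, 0]
        assert not sim.spikes[1].any()
        assert sim.v_pre[1][1, 0, 0] == pytest.approx(0.6 * decay + 0.6)


class TestGradients:
    def _tiny(self, rng, T=3):
        model = CSSNN.build("8-cs3-fc4-fc2", sample=2, T=T, seed=1)
        X = rng.uniform(0, 1, (2, 8))
        y = np.array([0, 1])
        return model, X, y

    def test_snn_gradients_match_finite_differences(self, rng):
        """Running the forward with the smooth arctangent spike makes the
        computed STBP gradients exact; check them against central
        differences of the smoothed loss."""
        model, X, y = self._tiny(rng)
        cfg = TrainConfig(epochs=1, T=3)
        smooth = lambda u: atan_surrogate(u, cfg.alpha)

        def loss():
            sim = forward_batch(model, X, 3, spike_fn=smooth)
            return compute_loss(sim.output_rates, y, "ce")[0]

        sim = forward_batch(model, X, 3, spike_fn=smooth)
        _, drates = compute_loss(sim.output_rates, y, "ce")
        grads = compute_gradients(model, sim, X, drates, cfg)
        eps = 1e-6
        for li, W in enumerate(model.weights):
            for i, j in [(0, 0), (1, 1), (W.shape[0] - 1, W.shape[1] - 1)]:
                W[i, j] += eps
                lp = loss()
                W[i, j] -= 2 * eps
                lm = loss()
                W[i, j] += eps
                fd = (lp - lm) / (2 * eps)
                assert fd == pytest.approx(grads["weights"][li][i, j], rel=1e-4, abs=1e-9)

    def test_encoder_gradient_estimator_modes(self, rng):
        """Strict masking zeroes the gradient on de-selected entries;
        straight-through passes the full spatial gradient to every real
        weight."""
        model, X, y = self._tiny(rng)
        sim = forward_batch(model, X, 3)
        _, drates = compute_loss(sim.output_rates, y, "ce")
        g_ste = compute_gradients(model, sim, X, drates, TrainConfig(T=3, grad_mode="ste"))
        g_strict = compute_gradients(
            model, sim, X, drates, TrainConfig(T=3, grad_mode="strict")
        )
        B = model.encoder.binary()
        assert (g_strict["encoder"][B == 0] == 0).all()
        np.testing.assert_allclose(g_strict["encoder"], g_ste["encoder"] * B)
        # the STE gradient reaches masked-out weights too
        assert np.abs(g_ste["encoder"][B == 0]).sum() > 0

    def test_encoder_gradient_is_spatial_only(self, rng):
        """The encoder projection is time-invariant, so its gradient is the
        outer product of the summed current-gradient with the input."""
        model, X, y = self._tiny(rng)
        sim = forward_batch(model, X, 3)
        _, drates = compute_loss(sim.output_rates, y, "ce")
        cfg = TrainConfig(T=3)
        g = compute_gradients(model, sim, X, drates, cfg)
        assert g["encoder"].shape == model.encoder.W.shape

    def test_zero_loss_gradient_only_clips(self, rng):
        model, X, y = self._tiny(rng)
        before = [w.copy() for w in model.weights]
        opt = AdamW(lr=1e-3)
        sim = forward_batch(model, X, 3)
        grads = compute_gradients(
            model, sim, X, np.zeros_like(sim.output_rates), TrainConfig(T=3)
        )
        opt.weight_decay = 0.0
        opt.step(model.weights, grads["weights"])
        for w, w0 in zip(model.weights, before):
            np.testing.assert_allclose(w, w0, atol=1e-12)


class TestLoss:
    def test_cross_entropy_gradient_shape_and_direction(self):
        rates = np.array([[0.8, 0.2], [0.1, 0.9]])
        y = np.array([0, 1])
        loss, grad = compute_loss(rates, y, "ce")
        assert loss > 0
        assert grad[0, 0] < 0 < grad[0, 1]  # push class-0 rate up

    def test_mse_zero_at_perfect_rates(self):
        rates = np.array([[1.0, 0.0]])
        loss, grad = compute_loss(rates, np.array([0]), "mse")
        assert loss == 0.0 and not grad.any()


class TestFit:
    def test_zero_epochs_leaves_model_unchanged(self, rng):
        model = CSSNN.build("8-cs3-fc4-fc2", sample=2, T=3, seed=1)
        w0 = [w.copy() for w in model.weights]
        enc0 = model.encoder.W.copy()
        X = rng.uniform(0, 1, (6, 8))
        fit(model, X, np.array([0, 1] * 3), TrainConfig(epochs=0, T=3))
        for w, w_ref in zip(model.weights, w0):
            np.testing.assert_array_equal(w, w_ref)
        np.testing.assert_array_equal(model.encoder.W, enc0)

    def test_constant_lr_when_decay_is_one(self, rng):
        model = CSSNN.build("8-cs3-fc4-fc2", sample=2, T=2, seed=1)
        X = rng.uniform(0, 1, (8, 8))
        y = np.array([0, 1] * 4)
        hist = fit(model, X, y, TrainConfig(epochs=3, lr_decay=1.0, T=2, batch_size=4))
        assert hist.lr.nunique() == 1

    def test_lr_decays_per_epoch(self, rng):
        model = CSSNN.build("8-cs3-fc4-fc2", sample=2, T=2, seed=1)
        X = rng.uniform(0, 1, (8, 8))
        y = np.array([0, 1] * 4)
        hist = fit(model, X, y, TrainConfig(epochs=3, lr_decay=0.1, T=2, batch_size=4))
        np.testing.assert_allclose(hist.lr, [1e-3, 1e-4, 1e-5])

    def test_empty_dataset_rejected(self):
        model = CSSNN.build("8-cs3-fc4-fc2", sample=2, T=2, seed=1)
        with pytest.raises(ValueError):
            fit(model, np.zeros((0, 8)), np.zeros(0, dtype=int), TrainConfig(T=2))

    def test_encoder_weights_stay_clipped_through_training(self, rng):
        model = CSSNN.build("12-cs4-fc4-fc2", sample=3, T=3, seed=2)
        X = rng.uniform(0, 1, (20, 12))
        y = rng.integers(0, 2, 20)
        opt = AdamW(lr=0.5)  # aggressive step to force excursions
        cfg = TrainConfig(T=3)
        for _ in range(5):
            train_step(model, X, y, cfg, opt)
            assert model.encoder.W.min() >= -1.0 and model.encoder.W.max() <= 1.0

    def test_loss_decreases_on_separable_task(self, sparse_data):
        Xtr, ytr, _, _ = sparse_data
        model = CSSNN.build("784-cs78-fc32-fc10", sample=10, T=5, seed=0)
        hist = fit(
            model, Xtr[:200], ytr[:200],
            TrainConfig(epochs=4, lr_decay=0.9, T=5, seed=0),
        )
        assert hist.loss.iloc[-1] < hist.loss.iloc[0]

    def test_reproducible_given_seed(self, rng):
        X = rng.uniform(0, 1, (36, 16))
        y = rng.integers(0, 2, 36)
        finals = []
        for _ in range(2):
            model = CSSNN.build("16-cs5-fc6-fc2", sample=3, T=3, seed=7)
            fit(model, X, y, TrainConfig(epochs=3, T=3, seed=7))
            finals.append((model.encoder.W.copy(), [w.copy() for w in model.weights]))
        np.testing.assert_array_equal(finals[0][0], finals[1][0])
        for a, b in zip(finals[0][1], finals[1][1]):
            np.testing.assert_array_equal(a, b)


class TestEvaluate:
    def test_counting(self, trained_cssnn, sparse_data):
        _, _, Xte, yte = sparse_data
        preds = trained_cssnn.predict(Xte)
        acc = evaluate_accuracy(trained_cssnn, Xte, yte)
        assert acc == pytest.approx(np.mean(preds == yte))

    def test_per_class_tallies_are_one_vs_all(self, trained_cssnn, sparse_data):
        _, _, Xte, yte = sparse_data
        acc, tallies = evaluate_accuracy(trained_cssnn, Xte, yte, per_class=True)
        preds = trained_cssnn.predict(Xte)
        for c, t in tallies.items():
            assert t["TP"] == int(np.sum((preds == c) & (yte == c)))
            assert t["TN"] == int(np.sum((preds != c) & (yte != c)))

    def test_empty_dataset_rejected(self, trained_cssnn):
        with pytest.raises(ValueError):
            evaluate_accuracy(trained_cssnn, np.zeros((0, 784)), np.zeros(0))


class TestSweep:
    def test_grid_shape_and_single_cell(self, sparse_data):
        Xtr, ytr, Xte, yte = sparse_data
        cfg = TrainConfig(epochs=2, lr_decay=0.9, T=4, seed=0)
        table = sweep(
            (Xtr[:100], ytr[:100]), (Xte[:50], yte[:50]), cfg,
            crs=[0.1], sparsities=[0.05, 0.01], hidden=[16], T=4,
        )
        assert len(table) == 2
        assert set(table.cr) == {0.1}
        # encoder OPs strictly decrease with Sample at fixed CR
        ordered = table.sort_values("sample")
        assert ordered.encoder_ops.is_monotonic_increasing
        assert table.pareto.any()

    def test_empty_grid_rejected(self, sparse_data):
        Xtr, ytr, Xte, yte = sparse_data
        with pytest.raises(ValueError):
            sweep((Xtr, ytr), (Xte, yte), TrainConfig(), crs=[], sparsities=[0.1])
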