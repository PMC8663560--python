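"""Network structure, gradient correctness, training mechanics."""

import numpy as np
import pytest

from adiposcan.nn import DenseNet3D, ModelConfig, infer, select_checkpoint, train_model
from adiposcan.nn.training import Adam, TrainingHistory, cyclic_exp_lr, multitask_loss

TOY_CFG = dict(growth_factor=4, init_kernel=3, init_filters=3, dense_blocks=2,
               layers_per_block=2, fc_widths=(24, 12, 6), dropout_rate=0.0)
TOY_DIMS = (6, 7, 8)


def _toy_net(seed=0):
    return DenseNet3D(ModelConfig(**TOY_CFG), TOY_DIMS, seed=seed)


def _toy_labels(n, rng):
    y = {h: rng.integers(0, 2, n) for h in ("sex", "diabetes", "prediabetes", "diabetes_ext")}
    y.update({h: rng.random(n) for h in ("age", "bmi", "insulin_sensitivity", "hba1c")})
    return y


class TestStructure:
    def test_embedding_dim_and_fc_widths(self):
        cfg = ModelConfig(layers_per_block=2)
        net = DenseNet3D(cfg, (12, 12, 14), seed=0)
        out = net.forward(np.zeros((2, 12, 12, 14), dtype=np.float32))
        assert out["embedding"].shape == (2, 128)
        assert cfg.fc_widths == (512, 256, 128)
        widths = [layer.params["W"].shape[0] for layer in net.fc if hasattr(layer, "params") and "W" in layer.params]
        assert widths == [512, 256, 128]

    def test_concatenative_growth(self):
        cfg = ModelConfig(layers_per_block=3)
        net = DenseNet3D(cfg, (12, 12, 14), seed=0)
        for entering, leaving in net.block_channel_counts():
            assert leaving == entering + cfg.layers_per_block * cfg.growth_factor
        assert cfg.growth_factor == 18

    def test_seeded_init_identical(self):
        a, b = _toy_net(3), _toy_net(3)
        for (la, na), (lb, nb) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(la.params[na], lb.params[nb])

    def test_param_count_is_config_function(self):
        assert _toy_net(0).n_parameters() == _toy_net(99).n_parameters()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(growth_factor=0)
        with pytest.raises(ValueError):
            ModelConfig(fc_widths=(128, 256, 512))
        with pytest.raises(ValueError):
            DenseNet3D(ModelConfig(), (0, 8, 8))

    def test_probability_pairs_sum_to_one(self, rng):
        net = _toy_net()
        preds = net.predict(rng.normal(size=(3, *TOY_DIMS)).astype(np.float32))
        for head in ("sex", "diabetes", "prediabetes", "diabetes_ext"):
            assert np.allclose(preds[head].sum(axis=1), 1.0, atol=1e-5)


class TestGradients:
    def test_input_and_param_gradients_match_finite_differences(self, rng):
        """Central-difference check of the full backward pass (train mode)."""
        net = _toy_net(1)
        x = rng.normal(size=(2, *TOY_DIMS))
        labels = {"sex": np.array([0, 1]), "diabetes": np.array([1, 0]),
                  "prediabetes": np.array([1, 1]), "diabetes_ext": np.array([0, 0])}

        def loss_of(xx):
            out = net.forward(xx.astype(np.float32), train=True)
            val, _ = multitask_loss(out, labels)
            return val

        out = net.forward(x.astype(np.float32), train=True)
        _, dlogits = multitask_loss(out, labels)
        dx = net.backward(dlogits)

        eps = 1e-2
        for idx in [(0, 2, 3, 4), (1, 0, 0, 0), (1, 5, 6, 7)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = (loss_of(xp) - loss_of(xm)) / (2 * eps)
            assert dx[idx] == pytest.approx(num, rel=0.15, abs=5e-4)

        params = net.parameters()
        pick = np.random.default_rng(5).choice(len(params), 4, replace=False)
        for k in pick:
            layer, name = params[k]
            arr = layer.params[name]
            i = np.unravel_index(0, arr.shape)
            net.forward(x.astype(np.float32), train=True)
            out = net.forward(x.astype(np.float32), train=True)
            _, dlogits = multitask_loss(out, labels)
            net.backward(dlogits)
            ana = layer.grads[name][i]
            orig = arr[i]
            arr[i] = orig + eps
            lp = loss_of(x)
            arr[i] = orig - eps
            lm = loss_of(x)
            arr[i] = orig
            assert ana == pytest.approx((lp - lm) / (2 * eps), rel=0.15, abs=5e-4)

    def test_loss_decreases_after_one_step(self, rng):
        net = _toy_net(2)
        x = rng.normal(size=(8, *TOY_DIMS)).astype(np.float32)
        labels = _toy_labels(8, rng)
        opt = Adam(net.parameters(), lr=1e-2)
        out = net.forward(x, train=True)
        l0, d = multitask_loss(out, labels)
        net.backward(d)
        opt.step()
        out = net.forward(x, train=True)
        l1, _ = multitask_loss(out, labels)
        assert l1 < l0


class TestTraining:
    def test_lr_schedule_starts_at_init_lr(self):
        cfg = ModelConfig()
        assert cyclic_exp_lr(0, cfg) == pytest.approx(cfg.init_lr)
        assert cfg.init_lr == 1e-4
        # exponential envelope decays over a full cycle
        assert cyclic_exp_lr(cfg.lr_cycle_len, cfg) < cfg.init_lr

    def test_divergence_aborts_with_diagnostic(self, rng):
        net = _toy_net(4)
        x = rng.normal(size=(4, *TOY_DIMS)).astype(np.float32)
        y = _toy_labels(4, rng)
        for layer, name in net.parameters():
            layer.params[name] = layer.params[name] * np.nan
        with pytest.raises(FloatingPointError):
            train_model(net, (x, y, None), (x, y, None), epochs=1, seed=0)

    def test_empty_fold_rejected(self, rng):
        net = _toy_net(4)
        x = rng.normal(size=(4, *TOY_DIMS)).astype(np.float32)
        y = _toy_labels(4, rng)
        with pytest.raises(ValueError):
            train_model(net, (x[:0], y, None), (x, y, None), epochs=1)

    def test_masked_labels_excluded_from_loss(self, rng):
        net = _toy_net(5)
        x = rng.normal(size=(4, *TOY_DIMS)).astype(np.float32)
        out = net.forward(x, train=False)
        y = {"age": np.array([0.2, 0.4, 0.6, 0.8])}
        full, _ = multitask_loss(out, y)
        masked, grads = multitask_loss(out, y, {"age": np.array([True, True, False, False])})
        expected = np.abs(out["age"][:2, 0] - y["age"][:2]).mean()
        assert masked == pytest.approx(expected, rel=1e-5)
        assert np.all(grads["age"][2:] == 0)


class TestSelection:
    def _history(self, scores):
        h = TrainingHistory()
        for i, s in enumerate(scores):
            h.epochs.append(i)
            h.train_loss.append(0.0)
            h.lr.append(1e-4)
            h.val_metrics.append({"auroc_diabetes": s})
            h.checkpoints.append({"epoch": i})
        return h

    def test_argmax(self):
        ep, state = select_checkpoint(self._history([0.6, 0.8, 0.7]))
        assert ep == 1 and state == {"epoch": 1}

    def test_tie_breaks_earliest(self):
        ep, _ = select_checkpoint(self._history([0.7, 0.7, 0.7]))
        assert ep == 0

    def test_single_checkpoint(self):
        ep, _ = select_checkpoint(self._history([0.5]))
        assert ep == 0

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            select_checkpoint(TrainingHistory())


class TestInference:
    def test_eval_mode_deterministic(self, rng):
        net = _toy_net(6)
        x = rng.normal(size=(3, *TOY_DIMS)).astype(np.float32)
        a = infer(net, x)
        b = infer(net, x)
        for k in a:
            assert np.array_equal(a[k], b[k])

    def test_embedding_matrix_shape(self, rng):
        net = _toy_net(6)
        x = rng.normal(size=(5, *TOY_DIMS)).astype(np.float32)
        assert infer(net, x)["embedding"].shape == (5, TOY_CFG["fc_widths"][-1])

    def test_dim_mismatch_rejected(self, rng):
        net = _toy_net(6)
        with pytest.raises(ValueError):
            infer(net, rng.normal(size=(2, 5, 5, 5)).astype(np.float32))

    def test_checkpoint_roundtrip(self, rng):
        net = _toy_net(7)
        x = rng.normal(size=(2, *TOY_DIMS)).astype(np.float32)
        state = net.snapshot()
        before = net.predict(x)
        other = _toy_net(8)
        other.load_state_dict(state)
        after = other.predict(x)
        for k in before:
            assert np.allclose(before[k], after[k], atol=1e-6)
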