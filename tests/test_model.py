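"""CNN building blocks against brute-force oracles, plus training contracts."""

import numpy as np
import pytest

from csecg import (
    BeatClassifier,
    ModelConfig,
    SegmentDataset,
    TrainConfig,
    build_model,
    conv_block,
    max_pool,
    temporal_transition,
)
from csecg.model import Conv1D, MaxPool, TemporalTransition


def brute_force_conv(x, W, b):
    """Direct evaluation of the convolution sum (same padding).

    x: (L, Cin); W: (Cin, k, F); returns (L, F) pre-activation.
    """
    Cin, k, F = W.shape
    L = x.shape[0]
    pad = (k - 1) // 2
    xp = np.pad(x, ((pad, pad), (0, 0)))
    out = np.zeros((L, F))
    for i in range(L):
        for f in range(F):
            acc = b[f]
            for m in range(k):
                for c in range(Cin):
                    acc += W[c, m, f] * xp[i + m, c]
            out[i, f] = acc
    return out


class TestConvolution:
    def test_matches_brute_force_sum(self, rng):
        x = rng.standard_normal((1, 20, 3))
        conv = Conv1D(3, 2, 5, rng, dtype=np.float64)
        out = conv.forward(x)
        expected = brute_force_conv(x[0], conv.W, conv.b)
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_hand_set_weights_kernel_3(self):
        x = np.arange(6, dtype=float).reshape(1, 6, 1)
        conv = Conv1D(1, 1, 3, np.random.default_rng(0), dtype=np.float64)
        conv.W[...] = np.array([1.0, 2.0, -1.0]).reshape(1, 3, 1)
        conv.b[...] = 0.5
        out = conv.forward(x)[0, :, 0]
        expected = brute_force_conv(x[0], conv.W, conv.b)[:, 0]
        np.testing.assert_allclose(out, expected, atol=1e-12)
        # interior point by hand: 1*x[1] + 2*x[2] - 1*x[3] + 0.5
        assert out[2] == pytest.approx(1 * 1 + 2 * 2 - 1 * 3 + 0.5)

    def test_same_padding_preserves_length(self, rng):
        out = conv_block(rng.standard_normal((2, 37, 4)), filters=6, kernel=5)
        assert out.shape == (2, 37, 6)

    def test_zero_input_zero_bias_gives_zero_preactivation(self, rng):
        conv = Conv1D(2, 3, 3, rng)
        out = conv.forward(np.zeros((1, 10, 2)))
        np.testing.assert_array_equal(out, 0.0)

    def test_kernel_longer_than_input_rejected(self, rng):
        conv = Conv1D(1, 1, 11, rng)
        with pytest.raises(ValueError):
            conv.forward(np.zeros((1, 5, 1)))

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            Conv1D(1, 1, 4, rng)


class TestMaxPool:
    def test_hand_example(self):
        x = np.array([1.0, 3.0, 2.0, 5.0]).reshape(1, 4, 1)
        np.testing.assert_array_equal(
            max_pool(x, 2, 2)[0, :, 0], [3.0, 5.0])

    def test_identity_with_unit_pool(self, rng):
        x = rng.standard_normal((2, 9, 3))
        np.testing.assert_array_equal(max_pool(x, 1, 1), x)

    def test_constant_input(self):
        out = max_pool(np.full((1, 10, 2), 1.5), 3, 2)
        np.testing.assert_array_equal(out, 1.5)

    def test_matches_brute_force_windows(self, rng):
        x = rng.standard_normal((3, 23, 4))
        R, T = 3, 2
        out = max_pool(x, R, T)
        n_out = (23 - R) // T + 1
        assert out.shape == (3, n_out, 4)
        for i in range(n_out):
            np.testing.assert_array_equal(
                out[:, i, :], x[:, i * T: i * T + R, :].max(axis=1))

    def test_pool_larger_than_input_rejected(self):
        with pytest.raises(ValueError):
            max_pool(np.zeros((1, 3, 1)), 5, 1)


class TestTemporalTransition:
    def test_output_channels_sum_branch_filters(self, rng):
        out = temporal_transition(rng.standard_normal((2, 30, 4)),
                                  branch_filters=(8, 8, 16))
        assert out.shape == (2, 30, 32)

    def test_length_preserved(self, rng):
        out = temporal_transition(rng.standard_normal((1, 50, 2)),
                                  branch_filters=(2, 2, 2))
        assert out.shape[1] == 50

    def test_concatenation_is_branchwise(self, rng):
        """Each channel slice equals its branch applied alone."""
        x = rng.standard_normal((2, 30, 4))
        module = TemporalTransition(4, (3, 5, 7), rng=np.random.default_rng(7))
        out = module.forward(x)
        start = 0
        for conv, bn, act in module.branches:
            width = conv.W.shape[2]
            alone = act.forward(bn.forward(conv.forward(x)))
            np.testing.assert_allclose(
                out[:, :, start: start + width], alone, atol=1e-12)
            start += width

    def test_branch_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            TemporalTransition(4, (8, 8), kernels=(1, 3, 11), rng=rng)


class TestBuildModel:
    def test_probabilities_normalised(self, rng):
        clf = build_model(ModelConfig.small())
        probs = clf.forward(rng.standard_normal((16, 400)))
        assert probs.shape == (16, 5)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_shape_contract(self, rng):
        clf = build_model(ModelConfig.small())
        assert clf.forward(rng.standard_normal((128, 400))).shape == (128, 5)

    def test_seeded_builds_identical(self, rng):
        a = build_model(ModelConfig.small(seed=42))
        b = build_model(ModelConfig.small(seed=42))
        x = rng.standard_normal((4, 400))
        np.testing.assert_array_equal(a.forward(x), b.forward(x))
        assert a.n_parameters == b.n_parameters

    def test_eval_forward_deterministic(self, rng):
        clf = build_model(ModelConfig.small())
        x = rng.standard_normal((4, 400))
        np.testing.assert_array_equal(clf.forward(x), clf.forward(x))

    def test_ablation_without_transitions(self, rng):
        config = ModelConfig(
            conv_blocks=((4, 3, 0.0),), transition_filters=(),
            fc_units=8, pool_size=2, pool_stride=2)
        clf = build_model(config)
        assert clf.forward(rng.standard_normal((2, 400))).shape == (2, 5)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(conv_blocks=((8, 4, 0.2),)),            # even kernel
            dict(conv_blocks=((8, 5, 0.9),)),            # dropout above cap
            dict(fc_dropout=0.9),
            dict(l2=-1.0),
            dict(transition_filters=((1, 1),)),          # branch mismatch
            dict(activation="tanh"),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            build_model(ModelConfig(**bad))


class TestTrainingPath:
    def _dataset(self, rng, n=96):
        X = rng.standard_normal((n, 400))
        y = rng.integers(0, 5, n)
        return SegmentDataset(X=X, y=y)

    def test_gradients_match_numerical(self, rng):
        """Backprop agrees with central finite differences."""
        from csecg.cs_loss import total_loss
        config = ModelConfig(
            conv_blocks=((2, 3, 0.0),), transition_filters=((1, 1, 1),),
            pool_size=2, pool_stride=2, fc_units=3, fc_dropout=0.0,
            l2=0.0, input_length=32, dtype="float64", seed=3)
        clf = BeatClassifier(config)
        X = rng.standard_normal((4, 32))
        y = np.array([0, 1, 2, 3])
        phi = np.array([1.0, 2.0, 0.5, 1.5, 1.0])

        probs = clf._forward_train(X[:, :, None], rng=None)
        clf._backward_sgd(probs, y, phi, lr=0.0)     # lr 0: only fill grads

        conv = clf.layers[0].conv
        analytic = conv.dW.copy()
        h = 1e-6
        for index in [(0, 0, 0), (0, 1, 1), (0, 2, 0)]:
            orig = conv.W[index]
            conv.W[index] = orig + h
            up = total_loss(clf._forward_train(X[:, :, None], None), y, phi)
            conv.W[index] = orig - h
            down = total_loss(clf._forward_train(X[:, :, None], None), y, phi)
            conv.W[index] = orig
            numeric = (up - down) / (2 * h)
            assert analytic[index] == pytest.approx(numeric, rel=1e-4, abs=1e-7)

    def test_loss_decreases_on_learnable_data(self, micro_model_config, rng):
        X = np.zeros((80, 400))
        y = np.tile(np.arange(5), 16)
        for i, c in enumerate(y):        # class-coded bump: trivially learnable
            X[i, 50 + 40 * c: 90 + 40 * c] = 1.0
        X += 0.05 * rng.standard_normal(X.shape)
        ds = SegmentDataset(X=X, y=y)
        clf = BeatClassifier(micro_model_config)
        history = clf.fit(ds, TrainConfig(epochs=8, batch_size=16, loss="ce"))
        assert history[-1]["loss"] < history[0]["loss"]

    def test_seeded_training_reproducible(self, micro_model_config, rng):
        ds = self._dataset(rng)
        runs = []
        for _ in range(2):
            clf = BeatClassifier(micro_model_config)
            clf.fit(ds, TrainConfig(epochs=1, batch_size=32))
            runs.append(clf.forward(ds.X[:8]))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_unknown_loss_rejected(self, micro_model_config, rng):
        clf = BeatClassifier(micro_model_config)
        with pytest.raises(ValueError):
            clf.fit(self._dataset(rng), TrainConfig(loss="focal"))

    def test_save_load_round_trip(self, micro_model_config, rng, tmp_path):
        ds = self._dataset(rng, n=32)
        clf = BeatClassifier(micro_model_config)
        clf.fit(ds, TrainConfig(epochs=1, batch_size=16))
        clf.save(tmp_path / "model")
        loaded = BeatClassifier.load(tmp_path / "model")
        np.testing.assert_array_equal(
            clf.forward(ds.X[:8]), loaded.forward(ds.X[:8]))
        assert loaded.n_parameters == clf.n_parameters
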