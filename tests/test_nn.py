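"""Gradient and mechanics checks of the numpy network core."""

import numpy as np
import pytest

from lncfuse.nn import SGD, Adam, BiLstmNet, ConvNet, clip_by_global_norm, train_network


def numerical_grad(f, arr, eps=1e-6, n_probe=8, rng=None):
    """Central-difference gradient at a few probed entries."""
    rng = rng or np.random.default_rng(0)
    flat = arr.reshape(-1)
    idx = rng.choice(flat.size, size=min(n_probe, flat.size), replace=False)
    out = {}
    for i in idx:
        old = flat[i]
        flat[i] = old + eps
        fp = f()
        flat[i] = old - eps
        fm = f()
        flat[i] = old
        out[int(i)] = (fp - fm) / (2 * eps)
    return out


class TestBiLstmGradients:
    def test_backprop_matches_numerical(self):
        rng = np.random.default_rng(42)
        net = BiLstmNet(vocab_size=9, embed_dim=3, units=4, dropout=0.0, rng=rng)
        tokens = np.array([[1, 5, 8, 2, 0], [3, 3, 7, 0, 0]])  # trailing padding
        y = np.array([1.0, 0.0])
        _, grads = net.loss_and_grads(tokens, y)

        def loss():
            cp, _ = net.forward(tokens)
            return -np.mean(y * np.log(cp + 1e-12) + (1 - y) * np.log(1 - cp + 1e-12))

        for name, g in grads.items():
            probes = numerical_grad(loss, net.params[name], rng=np.random.default_rng(1))
            for i, num in probes.items():
                ana = g.reshape(-1)[i]
                assert ana == pytest.approx(num, abs=1e-5), name

    def test_padding_is_inert(self):
        # extending sequences with padding must not change the output
        net = BiLstmNet(vocab_size=9, embed_dim=3, units=4, dropout=0.0)
        a = np.array([[1, 5, 8]])
        b = np.array([[1, 5, 8, 0, 0, 0]])
        cp_a, _ = net.forward(a)
        cp_b, _ = net.forward(b)
        assert cp_a[0] == pytest.approx(cp_b[0], abs=1e-12)

    def test_output_in_unit_interval(self):
        net = BiLstmNet(vocab_size=65, embed_dim=8, units=8)
        tokens = np.random.default_rng(0).integers(0, 65, size=(20, 30))
        cp, _ = net.forward(tokens)
        assert np.all((cp >= 0) & (cp <= 1))


class TestConvGradients:
    def test_backprop_matches_numerical(self):
        rng = np.random.default_rng(7)
        net = ConvNet(n_columns=30, filters=(3, 4), kernel=4, pool=2, dropout=0.0, rng=rng)
        X = np.zeros((2, 4, 30), dtype=np.int8)
        rows = rng.integers(0, 4, size=(2, 30))
        for b in range(2):
            X[b, rows[b], np.arange(30)] = 1
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        _, grads = net.loss_and_grads(X, y)

        def loss():
            probs, _ = net.forward(X)
            return -np.mean(np.sum(y * np.log(probs + 1e-12), axis=1))

        for name, g in grads.items():
            probes = numerical_grad(loss, net.params[name], rng=np.random.default_rng(2))
            for i, num in probes.items():
                ana = g.reshape(-1)[i]
                assert ana == pytest.approx(num, abs=1e-5), name

    def test_softmax_outputs_sum_to_one(self):
        net = ConvNet(n_columns=40, filters=(4, 4))
        X = np.zeros((5, 4, 40), dtype=np.int8)
        X[:, 0, :] = 1
        probs, _ = net.forward(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_receptive_field_check(self):
        with pytest.raises(ValueError, match="at least"):
            ConvNet(n_columns=10, kernel=8, pool=2)


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        rng = np.random.default_rng(0)
        # two token distributions: class 1 uses high tokens, class 0 low ones
        X = np.concatenate(
            [rng.integers(1, 8, size=(40, 20)), rng.integers(57, 64, size=(40, 20))]
        )
        y = np.concatenate([np.zeros(40), np.ones(40)])
        net = BiLstmNet(65, 8, 8, dropout=0.0, rng=np.random.default_rng(1))
        hist = train_network(net, X, y, Adam(1e-2), epochs=5, batch_size=16,
                             rng=np.random.default_rng(2))
        assert hist[-1] < hist[0]

    def test_clip_rescales_large_gradients(self):
        grads = {"a": np.array([3.0, 4.0])}
        clip_by_global_norm(grads, 1.0)
        assert np.linalg.norm(grads["a"]) == pytest.approx(1.0)
        grads = {"a": np.array([0.3, 0.4])}
        clip_by_global_norm(grads, 1.0)
        np.testing.assert_allclose(grads["a"], [0.3, 0.4])

    def test_sgd_momentum_step(self):
        params = {"w": np.array([1.0])}
        opt = SGD(lr=0.1, momentum=0.5)
        opt.step(params, {"w": np.array([1.0])})
        opt.step(params, {"w": np.array([1.0])})
        # steps: 0.1, then 0.1 * (0.5*1 + 1) = 0.15
        assert params["w"][0] == pytest.approx(1.0 - 0.1 - 0.15)
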