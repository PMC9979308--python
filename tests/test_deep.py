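"""Convolutional restoration net: forward, cost, gradients, training."""

import numpy as np
import pytest

from dictmri import deep, fourier, metrics
from dictmri import synthetic as syn

TOY_ARCH = ((3, 1, 4), (3, 4, 1))


class TestForward:
    def test_zero_net_maps_everything_to_zero(self, rng):
        net = deep.init_net(TOY_ARCH, seed=0)
        for w in net.weights:
            w[:] = 0.0
        assert not deep.forward(net, rng.random((8, 8))).any()

    def test_one_by_one_identity_layer(self, rng):
        net = deep.init_net(((1, 1, 1),), seed=0)
        net.weights[0][:] = 1.0
        net.biases[0][:] = 0.0
        x = rng.random((8, 8))
        np.testing.assert_allclose(deep.forward(net, x), x, atol=1e-12)

    def test_deterministic(self, rng):
        net = deep.init_net(TOY_ARCH, seed=1)
        x = rng.random((8, 8))
        np.testing.assert_array_equal(deep.forward(net, x), deep.forward(net, x))

    def test_residual_zero_net_is_identity(self, rng):
        net = deep.init_net(TOY_ARCH, seed=0, residual=True)
        for w in net.weights:
            w[:] = 0.0
        x = rng.random((8, 8))
        np.testing.assert_allclose(deep.forward(net, x), x, atol=1e-12)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            deep.init_net(((3, 1, 4), (3, 8, 1)))


class TestCost:
    def test_perfect_net_zero_cost(self, rng):
        net = deep.init_net(((1, 1, 1),), seed=0, residual=True)
        for w in net.weights:
            w[:] = 0.0
        x = rng.random((2, 8, 8))
        total, data, decay = deep.cost(net, x, x)
        assert total == 0.0 and data == 0.0 and decay == 0.0

    def test_constant_residual_closed_form(self):
        # h(x) - y = 0.1 everywhere -> data = (1/2) * mean(0.1^2) = 0.005
        net = deep.init_net(((1, 1, 1),), seed=0, residual=True)
        net.weights[0][:] = 0.0
        net.biases[0][:] = 0.1
        x = np.zeros((1, 8, 8))
        total, data, decay = deep.cost(net, x, x)
        assert data == pytest.approx(0.5 * 0.01)
        assert decay == 0.0

    def test_decay_excludes_biases_and_decomposes(self, rng):
        net = deep.init_net(TOY_ARCH, weight_decay=0.5, seed=2)
        net.biases[0][:] = 3.0  # biases must not enter the decay term
        x, y = rng.random((2, 8, 8)), rng.random((2, 8, 8))
        total, data, decay = deep.cost(net, x, y)
        expected_decay = 0.5 * 0.5 * sum(np.sum(w**2) for w in net.weights)
        assert decay == pytest.approx(expected_decay)
        assert total == pytest.approx(data + decay, abs=1e-9)

    def test_empty_batch_rejected(self):
        net = deep.init_net(TOY_ARCH)
        with pytest.raises(ValueError):
            deep.cost(net, np.zeros((0, 8, 8)), np.zeros((0, 8, 8)))


class TestGradients:
    @pytest.mark.parametrize("residual", [False, True])
    def test_matches_central_finite_differences(self, residual, rng):
        net = deep.init_net(TOY_ARCH, weight_decay=0.1, seed=0, residual=residual)
        x, y = rng.random((2, 8, 8)), rng.random((2, 8, 8))
        dWs, dbs = deep.gradients(net, x, y)
        eps = 1e-6
        checks = 0
        for l in range(len(net.weights)):
            for _ in range(10):
                idx = tuple(rng.integers(0, s) for s in net.weights[l].shape)
                up, down = net.copy(), net.copy()
                up.weights[l][idx] += eps
                down.weights[l][idx] -= eps
                fd = (deep.cost(up, x, y)[0] - deep.cost(down, x, y)[0]) / (2 * eps)
                assert dWs[l][idx] == pytest.approx(fd, rel=1e-4, abs=1e-10)
                checks += 1
            bidx = int(rng.integers(0, net.biases[l].size))
            up, down = net.copy(), net.copy()
            up.biases[l][bidx] += eps
            down.biases[l][bidx] -= eps
            fd = (deep.cost(up, x, y)[0] - deep.cost(down, x, y)[0]) / (2 * eps)
            assert dbs[l][bidx] == pytest.approx(fd, rel=1e-4, abs=1e-10)
        assert checks == 20

    def test_zero_learning_rate_leaves_net_unchanged(self, rng):
        net = deep.init_net(TOY_ARCH, seed=3)
        x, y = rng.random((1, 8, 8)), rng.random((1, 8, 8))
        net2 = deep.sgd_step(net, x, y, learning_rate=0.0)
        for w, w2 in zip(net.weights, net2.weights):
            np.testing.assert_array_equal(w, w2)

    def test_scalar_net_matches_closed_form_update(self):
        # single 1x1 conv on a 1x1 image: h = w*x, cost = 0.5*(w*x - y)^2,
        # so one step gives w' = w - alpha * (w*x - y) * x
        net = deep.init_net(((1, 1, 1),), learning_rate=0.2, seed=0)
        net.weights[0][:] = 0.7
        x, y = np.full((1, 1, 1), 0.5), np.full((1, 1, 1), 1.0)
        net2 = deep.sgd_step(net, x, y)
        w = 0.7
        expected = w - 0.2 * (w * 0.5 - 1.0) * 0.5
        assert net2.weights[0].item() == pytest.approx(expected, abs=1e-12)


class TestTraining:
    def _pairs(self, n, rate=0.4, size=32):
        out = []
        for i in range(n):
            ph = syn.make_phantom(syn.PhantomSpec(height=size, width=size, seed=100 + i))
            mask = syn.make_mask(syn.MaskSpec(sampling_rate=rate, seed=i), ph.shape)
            s = syn.simulate_acquisition(ph, mask)
            out.append((np.clip(fourier.zero_filled(s.data), 0, 1), ph))
        return out

    def test_overfits_single_pair(self):
        # capacity check: one pair, long training, final data cost < 1% of
        # the untrained net's cost
        pairs = self._pairs(1)
        arch = ((9, 1, 32), (1, 32, 16), (5, 16, 1))
        net = deep.init_net(arch, learning_rate=0.1, seed=0)
        initial = deep.cost(net, pairs[0][0], pairs[0][1])[1]
        net, log = deep.train_deep(pairs, 1, 0, epochs=1000, net=net, seed=0, momentum=0.9)
        assert log.data[-1] < 0.01 * initial

    def test_weight_decay_shrinks_weights(self):
        pairs = self._pairs(2)
        norms = {}
        for lam in (0.0, 1e3):
            # learning rate small enough that the lam=1e3 decay step (factor
            # 1 - lr*lam per update) shrinks instead of oscillating
            net = deep.init_net(TOY_ARCH, learning_rate=1e-4, weight_decay=lam, seed=0)
            net, _ = deep.train_deep(pairs, 2, 0, epochs=20, net=net, seed=0)
            norms[lam] = sum(np.linalg.norm(w) for w in net.weights)
        assert norms[1e3] < norms[0.0]

    def test_training_log_deterministic_under_seed(self):
        pairs = self._pairs(3)
        logs = []
        for _ in range(2):
            net = deep.init_net(TOY_ARCH, learning_rate=0.1, seed=5, residual=True)
            _, log = deep.train_deep(pairs, 2, 1, epochs=5, net=net, seed=5, momentum=0.9)
            logs.append(log)
        assert logs[0].total == logs[1].total
        assert logs[0].test_psnr == logs[1].test_psnr

    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError):
            deep.train_deep(self._pairs(2), 2, 1, epochs=1)


class TestReconstruction:
    def test_identity_net_full_sampling_recovers_truth(self, phantom64):
        net = deep.init_net(((1, 1, 1),), seed=0, residual=True)
        net.weights[0][:] = 0.0  # identity via the skip path
        s = syn.simulate_acquisition(phantom64, np.ones_like(phantom64, bool))
        out = deep.reconstruct_deep(s, net)
        assert np.abs(np.real(out) - phantom64).max() < 1e-6

    def test_data_consistency_exact(self, sample40, rng):
        net = deep.init_net(TOY_ARCH, seed=0, residual=True)
        out = deep.reconstruct_deep(sample40, net)
        k = fourier.fft2c(out)
        assert np.abs(k[sample40.mask] - sample40.data[sample40.mask]).max() < 1e-10
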