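"""Network construction, forward/backward correctness, and persistence."""

import numpy as np
import pytest

from nucseg import nn
from nucseg.architecture import rsnn_spec
from nucseg.network import SegmentationNetwork, apply_skip, build_rsnn


@pytest.fixture(scope="module")
def tiny_net():
    return build_rsnn(rsnn_spec(1 / 16), seed=11)


class TestConstruction:
    def test_conv_and_skip_census(self, tiny_net):
        assert tiny_net.n_conv_layers == 20
        assert tiny_net.n_skips == 4

    def test_full_width_parameter_total(self):
        net = build_rsnn(rsnn_spec(1), seed=0)
        assert sum(p.size for p in net.parameters) == 15_279_174

    def test_no_skip_variant_has_same_parameters(self):
        n_add = sum(p.size for p in build_rsnn(rsnn_spec(1 / 8), seed=0).parameters)
        n_none = sum(p.size for p in
                     build_rsnn(rsnn_spec(1 / 8, skip_mode="none"), seed=0).parameters)
        assert n_add == n_none

    def test_seeded_initialization_is_reproducible(self):
        a = build_rsnn(rsnn_spec(1 / 16), seed=5)
        b = build_rsnn(rsnn_spec(1 / 16), seed=5)
        for pa, pb in zip(a.parameters, b.parameters):
            assert np.array_equal(pa.data, pb.data)
        c = build_rsnn(rsnn_spec(1 / 16), seed=6)
        assert not np.array_equal(a.parameters[0].data, c.parameters[0].data)


class TestForward:
    def test_probabilities_sum_to_one(self, tiny_net, rng):
        x = rng.random((2, 48, 48, 3), dtype=np.float32)
        p = tiny_net.forward_logits(x)
        probs = nn.softmax(p)
        assert np.allclose(probs.sum(-1), 1.0, atol=1e-6)

    def test_fully_convolutional_output_shapes(self, tiny_net, rng):
        """Output spatial size always equals input size, odd sizes included."""
        for h, w in [(64, 64), (100, 60), (125, 125)]:
            x = rng.random((1, h, w, 3), dtype=np.float32)
            assert tiny_net.forward(x).shape == (1, h, w, 2)

    def test_full_size_tile_forward(self, rng):
        """A full 1000x1000 tile maps to a 1000x1000x2 probability map."""
        net = build_rsnn(rsnn_spec(1 / 16), seed=1)
        x = rng.random((1000, 1000, 3), dtype=np.float32)
        probs = net.forward(x)
        assert probs.shape == (1000, 1000, 2)
        assert np.allclose(probs.sum(-1), 1.0, atol=1e-6)

    def test_deterministic_forward(self, tiny_net, rng):
        x = rng.random((1, 32, 32, 3), dtype=np.float32)
        assert np.array_equal(tiny_net.forward(x), tiny_net.forward(x))

    def test_rejects_bad_rank(self, tiny_net):
        with pytest.raises(ValueError):
            tiny_net.forward_logits(np.zeros((8, 8), dtype=np.float32))


class TestSkipAlgebra:
    def test_add_identities(self, rng):
        a = rng.random((1, 4, 4, 3))
        z = np.zeros_like(a)
        assert np.array_equal(nn.Add.forward(a, z), a)
        assert np.array_equal(nn.Add.forward(z, a), a)

    def test_elementwise_sum(self):
        local = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 2, 2, 1)
        skip = np.array([[10.0, 0.0], [0.0, 10.0]]).reshape(1, 2, 2, 1)
        out = nn.Add.forward(local, skip)
        assert np.array_equal(out.reshape(2, 2), [[11.0, 2.0], [3.0, 14.0]])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            nn.Add.forward(np.zeros((1, 4, 4, 2)), np.zeros((1, 4, 4, 3)))

    def test_apply_skip_dispatch(self, rng):
        a, b = rng.random((1, 3, 3, 2)), rng.random((1, 3, 3, 2))
        assert np.array_equal(apply_skip(a, b, "add"), a + b)
        assert apply_skip(a, b, "concat").shape == (1, 3, 3, 4)
        with pytest.raises(ValueError):
            apply_skip(a, b, "gated")

    def test_concat_stacks_channels(self, rng):
        a, b = rng.random((1, 4, 4, 2)), rng.random((1, 4, 4, 3))
        out = nn.Concat.forward(a, b)
        assert out.shape == (1, 4, 4, 5)
        da, db = nn.Concat.backward(out, 2)
        assert np.array_equal(da, a) and np.array_equal(db, b)


class TestPooling:
    def test_unpool_restores_odd_presize(self, rng):
        pool = nn.MaxPool2x2()
        unpool = nn.MaxUnpool2x2(pool)
        x = rng.random((1, 5, 7, 2), dtype=np.float32)
        y = pool.forward(x, training=False)
        assert y.shape == (1, 2, 3, 2)
        up = unpool.forward(y, training=False)
        assert up.shape == x.shape

    def test_unpool_places_values_at_argmax_positions(self):
        pool = nn.MaxPool2x2()
        unpool = nn.MaxUnpool2x2(pool)
        x = np.array([[1, 9, 2, 3], [4, 5, 6, 7],
                      [8, 0, 1, 2], [3, 4, 5, 6]], dtype=np.float32)
        x = x.reshape(1, 4, 4, 1)
        y = pool.forward(x, training=False)
        assert y.reshape(-1).tolist() == [9, 7, 8, 6]
        up = unpool.forward(y, training=False)
        expected = np.zeros((4, 4), dtype=np.float32)
        expected[0, 1], expected[1, 3], expected[2, 0], expected[3, 3] = 9, 7, 8, 6
        assert np.array_equal(up.reshape(4, 4), expected)

    def test_nearest_mode_upsamples(self, rng):
        pool = nn.MaxPool2x2()
        unpool = nn.MaxUnpool2x2(pool, mode="nearest")
        x = rng.random((1, 6, 6, 1), dtype=np.float32)
        y = pool.forward(x, training=False)
        up = unpool.forward(y, training=False)
        assert up.shape == x.shape
        assert np.array_equal(up[0, :2, :2, 0], np.full((2, 2), y[0, 0, 0, 0]))


class TestGradients:
    @pytest.mark.parametrize("skip_mode", ["add", "concat", "none"])
    def test_backprop_matches_numerical_gradient(self, skip_mode):
        """Spot-check analytic vs central-difference gradients end to end."""
        net = SegmentationNetwork(rsnn_spec(1 / 16, skip_mode=skip_mode),
                                  seed=3, dtype=np.float64)
        # shift activations positive: at a ReLU zero or a pooling-window tie
        # the loss is non-differentiable and central differences diverge
        # from the (valid) subgradient, so the check runs away from kinks
        for kind, node in net.nodes:
            if kind == "conv" and node.relu is not None:
                node.bn.beta.data[:] = 0.7
        rng = np.random.default_rng(0)
        x = rng.random((2, 16, 16, 3))
        t = rng.integers(0, 2, (2, 16, 16))

        def loss_fn():
            logits = net.forward_logits(x, training=True)
            return nn.softmax_cross_entropy(logits, t)

        _, dl = loss_fn()
        net.zero_grad()
        net.backward(dl)
        check = np.random.default_rng(1)
        for p in net.parameters:
            # conv biases feeding BN have an exactly-zero gradient that
            # drowns in finite-difference noise; check weights and BN terms
            if not p.is_weight and p.name.endswith(".bias"):
                continue
            flat = p.data.reshape(-1)
            for idx in check.integers(0, flat.size, 2):
                eps, old = 1e-5, flat[idx]
                flat[idx] = old + eps
                lp, _ = loss_fn()
                flat[idx] = old - eps
                lm, _ = loss_fn()
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                ana = p.grad.reshape(-1)[idx]
                assert abs(num - ana) <= 1e-6 * max(1.0, abs(num)), p.name

    def test_gradient_reaches_every_parameter(self):
        """One backward pass on a toy batch touches all trainable tensors."""
        net = build_rsnn(rsnn_spec(1 / 16), seed=2)
        rng = np.random.default_rng(4)
        x = rng.random((2, 64, 64, 3)).astype(np.float32)
        t = rng.integers(0, 2, (2, 64, 64))
        logits = net.forward_logits(x, training=True)
        _, dl = nn.softmax_cross_entropy(logits, t)
        net.zero_grad()
        net.backward(dl)
        dead = [p.name for p in net.parameters
                if not np.any(p.grad) and not p.name.endswith(".bias")]
        assert dead == []


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        net = build_rsnn(rsnn_spec(1 / 16), seed=9)
        x = rng.random((1, 32, 32, 3), dtype=np.float32)
        before = net.forward(x)
        path = tmp_path / "ckpt.npz"
        net.save(path)
        restored = SegmentationNetwork.load(path)
        assert np.allclose(restored.forward(x), before, atol=1e-7)
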