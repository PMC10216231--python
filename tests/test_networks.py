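"""Network tests: table shape traces, AE contract, EMA algebra, gradients."""

import numpy as np
import pytest

from decspeech.nn.layers import (
    BatchNorm, Conv2d, Dropout, ELU, GlobalAvgPool, Linear, MaxPool2d,
    ReLU, Sequential, Sigmoid,
)
from decspeech.nn.networks import (
    AENetwork, DESK_INPUT, DESK_WIDTHS, FULL_WIDTHS, FusionHead, StudentCNN,
    ae_forward, cnn_forward, ema_update, fuse_and_classify, shape_trace, softmax,
)

FULL_TRACE = [
    ("input", (256, 256, 3)),
    ("3x(conv1+bn+relu)", (256, 256, 32)),
    ("max_pool", (128, 128, 32)),
    ("3x(conv2+bn+relu)", (128, 128, 64)),
    ("max_pool", (64, 64, 64)),
    ("conv3+bn+relu", (62, 62, 128)),
    ("conv4+bn+relu", (62, 62, 64)),
    ("conv5+bn+relu", (62, 62, 32)),
    ("sum_and_average", (32,)),
    ("full_connection", (8,)),
]


class TestShapeTrace:
    def test_full_scale_trace_reproduces_published_table(self):
        assert shape_trace() == FULL_TRACE

    def test_desk_scale_follows_same_rules(self):
        rows = dict(shape_trace(DESK_INPUT, DESK_WIDTHS))
        assert rows["input"] == (64, 64, 3)
        assert rows["3x(conv1+bn+relu)"] == (64, 64, 8)
        assert rows["conv3+bn+relu"] == (14, 14, 32)   # 16 - 2, unpadded
        assert rows["sum_and_average"] == (32,)

    def test_real_desk_forward_matches_trace_embedding(self):
        net = StudentCNN(DESK_INPUT, DESK_WIDTHS, seed=0)
        x = np.random.default_rng(0).standard_normal((2, 64, 64, 3))
        emb = net.forward(x, train=False)
        assert emb.shape == (2, 32)

    def test_wrong_input_shape_names_expected_and_got(self):
        net = StudentCNN(DESK_INPUT, DESK_WIDTHS, seed=0)
        with pytest.raises(ValueError, match=r"\(64, 64, 3\)"):
            net.forward(np.zeros((2, 32, 32, 3)), train=False)

    def test_eval_mode_forward_is_deterministic(self):
        net = StudentCNN(DESK_INPUT, DESK_WIDTHS, seed=1)
        x = np.random.default_rng(1).standard_normal((64, 64, 3))
        a = cnn_forward(x, net)
        b = cnn_forward(x, net)
        assert np.array_equal(a, b)


class TestAutoencoder:
    def test_bottleneck_32_and_reconstruction_384_in_unit_interval(self):
        ae = AENetwork(dropout=0.2, seed=0)
        x = np.random.default_rng(0).random((5, 384))
        z, r = ae.forward(x, train=False)
        assert z.shape == (5, 32)
        assert r.shape == (5, 384)
        assert r.min() > 0 and r.max() < 1

    def test_single_vector_api(self):
        ae = AENetwork(seed=0)
        z, r = ae_forward(np.random.default_rng(1).random(384), ae)
        assert z.shape == (32,) and r.shape == (384,)

    def test_eval_determinism(self):
        ae = AENetwork(dropout=0.5, seed=2)
        x = np.random.default_rng(2).random((3, 384))
        assert np.array_equal(ae.forward(x, False)[1], ae.forward(x, False)[1])

    def test_wrong_width_rejected(self):
        with pytest.raises(ValueError, match="384"):
            AENetwork(seed=0).forward(np.zeros((2, 100)), train=False)


class TestFusionAndSoftmax:
    def test_probabilities_sum_to_one(self):
        head = FusionHead(seed=0)
        probs = fuse_and_classify(np.random.default_rng(0).random((4, 32)),
                                  np.random.default_rng(1).random((4, 32)), head)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.min() >= 0

    def test_zero_weights_give_uniform_probabilities(self):
        head = FusionHead(seed=0)
        for layer, name in head.net.named_params():
            layer.params[name][...] = 0.0
        probs = fuse_and_classify(np.ones((3, 32)), np.ones((3, 32)), head)
        assert np.allclose(probs, 0.5)

    def test_softmax_closed_form_logit_gap(self):
        for c in (0.0, 1.0, -2.5, 7.0):
            p = softmax(np.array([[1.3, 1.3 + c]]))
            assert np.isclose(p[0, 1] / p[0, 0], np.exp(c), rtol=1e-12)

    def test_dimension_mismatch_raises(self):
        head = FusionHead(seed=0)
        with pytest.raises(ValueError):
            fuse_and_classify(np.zeros((2, 32)), np.zeros((3, 32)), head)
        with pytest.raises(ValueError):
            head.forward(np.zeros((2, 50)), train=False)


class TestEMA:
    def _states(self, dtype=np.float64):
        rng = np.random.default_rng(0)
        tea = {"w": rng.standard_normal((3, 4)).astype(dtype),
               "b": rng.standard_normal(4).astype(dtype)}
        stu = {"w": rng.standard_normal((3, 4)).astype(dtype),
               "b": rng.standard_normal(4).astype(dtype)}
        return tea, stu

    def test_alpha_one_leaves_teacher_unchanged(self):
        tea, stu = self._states()
        before = {k: v.copy() for k, v in tea.items()}
        ema_update(tea, stu, 1.0)
        assert all(np.array_equal(tea[k], before[k]) for k in tea)

    def test_alpha_zero_copies_student(self):
        tea, stu = self._states()
        ema_update(tea, stu, 0.0)
        assert all(np.array_equal(tea[k], stu[k]) for k in tea)

    def test_geometric_decay_matches_closed_form(self):
        tea, stu = self._states()
        start = {k: v.copy() for k, v in tea.items()}
        for _ in range(10):
            ema_update(tea, stu, 0.99)
        for k in tea:
            expected = stu[k] + 0.99 ** 10 * (start[k] - stu[k])
            assert np.allclose(tea[k], expected, atol=1e-10)

    def test_equal_networks_stay_equal(self):
        _, stu = self._states()
        tea = {k: v.copy() for k, v in stu.items()}
        ema_update(tea, stu, 0.37)
        assert all(np.allclose(tea[k], stu[k], atol=1e-14) for k in tea)

    def test_structure_mismatch_raises(self):
        tea, stu = self._states()
        del stu["b"]
        with pytest.raises(ValueError):
            ema_update(tea, stu, 0.5)
        tea2, stu2 = self._states()
        stu2["w"] = np.zeros((2, 2))
        with pytest.raises(ValueError):
            ema_update(tea2, stu2, 0.5)


def relative_error(a, b):
    # scale by the gradient's overall magnitude; exactly-cancelled
    # gradients (e.g. a bias immediately absorbed by batch norm) are
    # handled by the absolute floor
    denom = max(np.abs(a).max(), np.abs(b).max(), 1e-3)
    return np.abs(a - b).max() / denom


def check_param_gradients(net, x, rtol=1e-4, eps=1e-6):
    """Finite-difference check of every parameter gradient.

    Scalar loss: sum(out * w0) with a fixed random weighting, so the
    output gradient is w0.
    """
    out = net.forward(x, train=True)
    w0 = np.random.default_rng(99).standard_normal(out.shape)
    net.zero_grad()
    net.forward(x, train=True)
    net.backward(w0)
    for layer, name in net.named_params():
        analytic = layer.grads[name]
        p = layer.params[name]
        numeric = np.zeros_like(p)
        flat_p, flat_n = p.ravel(), numeric.ravel()
        for i in range(flat_p.size):
            orig = flat_p[i]
            flat_p[i] = orig + eps
            lp = float(np.sum(net.forward(x, train=True) * w0))
            flat_p[i] = orig - eps
            lm = float(np.sum(net.forward(x, train=True) * w0))
            flat_p[i] = orig
            flat_n[i] = (lp - lm) / (2 * eps)
        assert relative_error(analytic, numeric) < rtol, (type(layer).__name__, name)


class TestGradients:
    def test_conv_bn_relu_pool_chain(self):
        f64 = dict(dtype=np.float64)
        rng = np.random.default_rng(5)
        net = Sequential(
            Conv2d(2, 3, rng=rng, **f64), BatchNorm(3, **f64), ReLU(),
            MaxPool2d(),
            Conv2d(3, 2, padding="valid", rng=rng, **f64), BatchNorm(2, **f64), ReLU(),
            GlobalAvgPool(),
        )
        x = np.random.default_rng(6).standard_normal((3, 2, 6, 6))
        check_param_gradients(net, x)

    def test_dense_bn_elu_sigmoid_chain(self):
        f64 = dict(dtype=np.float64)
        rng = np.random.default_rng(7)
        net = Sequential(
            Linear(5, 7, rng=rng, **f64), BatchNorm(7, **f64), ELU(),
            Linear(7, 4, rng=rng, **f64), Sigmoid(),
        )
        x = np.random.default_rng(8).standard_normal((6, 5))
        check_param_gradients(net, x)

    def test_input_gradient_of_linear_chain(self):
        rng = np.random.default_rng(9)
        net = Sequential(Linear(4, 3, rng=rng, dtype=np.float64), ELU())
        x = np.random.default_rng(10).standard_normal((2, 4))
        w0 = np.random.default_rng(11).standard_normal((2, 3))
        net.forward(x, train=True)
        dx = net.backward(w0)
        numeric = np.zeros_like(x)
        eps = 1e-6
        for i in np.ndindex(x.shape):
            xp = x.copy(); xp[i] += eps
            xm = x.copy(); xm[i] -= eps
            numeric[i] = (np.sum(net.forward(xp, True) * w0)
                          - np.sum(net.forward(xm, True) * w0)) / (2 * eps)
        assert relative_error(dx, numeric) < 1e-6


class TestStateDict:
    def test_roundtrip_restores_forward(self):
        net = AENetwork(dropout=0.3, seed=4)
        x = np.random.default_rng(4).random((2, 384))
        ref = net.forward(x, train=False)
        state = {k: v.copy() for k, v in net.state_dict().items()}
        other = AENetwork(dropout=0.3, seed=99)
        other.load_state_dict(state)
        out = other.forward(x, train=False)
        assert np.array_equal(ref[0], out[0]) and np.array_equal(ref[1], out[1])

    def test_mismatched_keys_rejected(self):
        a = Sequential(Linear(3, 2))
        b = Sequential(Linear(3, 2), ReLU(), Linear(2, 2))
        with pytest.raises(ValueError):
            b.load_state_dict(a.state_dict())

    def test_dropout_probability_validated(self):
        with pytest.raises(ValueError):
            Dropout(1.0)
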