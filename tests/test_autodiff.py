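import numpy as np
import pytest

from symseg_da.autodiff import Tensor, astensor, concat, no_grad
from symseg_da.autodiff import functional as F
from symseg_da.autodiff import nn
from symseg_da.autodiff.optim import Adam


def numeric_grad(fn, x, eps=1e-3):
    """Central finite differences of sum(fn(x)) w.r.t. x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (float(fn(Tensor(xp)).sum().data) - float(fn(Tensor(xm)).sum().data)) / (2 * eps)
    return g


def check_grad(fn, x, tol=5e-2):
    xt = Tensor(x, requires_grad=True)
    fn(xt).sum().backward()
    num = numeric_grad(fn, x)
    scale = max(np.abs(num).max(), 1e-6)
    assert np.abs(xt.grad - num).max() / scale < tol


@pytest.fixture()
def x34(rng):
    return rng.normal(0, 1, (3, 4)).astype(np.float32)


class TestElementwiseGrads:
    def test_add_mul_broadcast(self, rng, x34):
        b = Tensor(rng.normal(0, 1, (1, 4)).astype(np.float32), requires_grad=True)
        xt = Tensor(x34, requires_grad=True)
        ((xt + b) * b).sum().backward()
        assert b.grad.shape == (1, 4)
        assert xt.grad.shape == (3, 4)

    @pytest.mark.parametrize("op", ["tanh", "sigmoid", "relu", "abs", "exp"])
    def test_unary(self, rng, x34, op):
        check_grad(lambda t: getattr(t, op)(), x34 + 2.0)  # shift away from kinks

    def test_log(self, rng):
        x = rng.uniform(0.5, 2.0, (3, 3)).astype(np.float32)
        check_grad(lambda t: t.log(), x)

    def test_pow(self, rng):
        x = rng.uniform(0.5, 2.0, (3, 3)).astype(np.float32)
        check_grad(lambda t: t.pow(1.7), x)

    def test_div(self, rng, x34):
        d = Tensor(rng.uniform(1.0, 2.0, (3, 4)).astype(np.float32))
        check_grad(lambda t: t / d, x34)

    def test_clip_passthrough_gradient(self):
        x = Tensor(np.array([-2.0, 0.5, 2.0], np.float32), requires_grad=True)
        x.clip(0.0, 1.0).sum().backward()
        assert np.array_equal(x.grad, [0.0, 1.0, 0.0])

    def test_leaky_relu(self, rng, x34):
        check_grad(lambda t: t.leaky_relu(0.2), x34 + 0.7)


class TestReductionsAndShapes:
    def test_sum_axis(self, rng, x34):
        check_grad(lambda t: t.sum(axis=1), x34)

    def test_mean_keepdims(self, rng, x34):
        check_grad(lambda t: t.mean(axis=(0, 1), keepdims=True), x34)

    def test_max_axis(self, rng):
        x = rng.normal(0, 1, (2, 5)).astype(np.float32)
        x += np.arange(10).reshape(2, 5) * 0.01  # break ties
        check_grad(lambda t: t.max(axis=1, keepdims=True), x)

    def test_reshape(self, rng, x34):
        check_grad(lambda t: t.reshape(4, 3) * 2.0, x34)

    def test_concat(self, rng):
        a = Tensor(rng.normal(0, 1, (2, 3)).astype(np.float32), requires_grad=True)
        b = Tensor(rng.normal(0, 1, (2, 2)).astype(np.float32), requires_grad=True)
        concat([a, b], axis=1).sum().backward()
        assert a.grad.shape == (2, 3) and b.grad.shape == (2, 2)
        assert np.all(a.grad == 1.0) and np.all(b.grad == 1.0)


class TestConvGrads:
    def test_conv2d_input_grad(self, rng):
        W = Tensor(rng.normal(0, 0.5, (3, 2, 3, 3)).astype(np.float32))
        x = rng.normal(0, 1, (2, 2, 6, 6)).astype(np.float32)
        check_grad(lambda t: F.conv2d(t, W, None, stride=2, pad=1), x)

    def test_conv2d_weight_and_bias_grad(self, rng):
        x = Tensor(rng.normal(0, 1, (2, 2, 6, 6)).astype(np.float32))
        w0 = rng.normal(0, 0.5, (3, 2, 3, 3)).astype(np.float32)
        b0 = rng.normal(0, 0.5, (3,)).astype(np.float32)
        check_grad(lambda wt: F.conv2d(x, wt, None, stride=1, pad=1), w0)
        W = Tensor(w0)
        check_grad(lambda bt: F.conv2d(x, W, bt, stride=1, pad=1), b0)

    def test_conv_transpose_grads(self, rng):
        x0 = rng.normal(0, 1, (2, 2, 5, 5)).astype(np.float32)
        w0 = rng.normal(0, 0.5, (2, 3, 4, 4)).astype(np.float32)
        W = Tensor(w0)
        check_grad(lambda t: F.conv_transpose2d(t, W, None, stride=2, pad=1), x0)
        x = Tensor(x0)
        check_grad(lambda wt: F.conv_transpose2d(x, wt, None, stride=2, pad=1), w0)

    def test_conv_transpose_output_size(self):
        x = Tensor(np.zeros((1, 4, 16, 16), np.float32))
        W = Tensor(np.zeros((4, 2, 4, 4), np.float32))
        assert F.conv_transpose2d(x, W, None, stride=2, pad=1).shape == (1, 2, 32, 32)

    def test_depthwise_grads(self, rng):
        x0 = rng.normal(0, 1, (2, 3, 6, 6)).astype(np.float32)
        w0 = rng.normal(0, 0.5, (3, 3, 3)).astype(np.float32)
        W = Tensor(w0)
        check_grad(lambda t: F.depthwise_conv2d(t, W, None, stride=1, pad=1), x0)
        x = Tensor(x0)
        check_grad(lambda wt: F.depthwise_conv2d(x, wt, None, stride=2, pad=1), w0)

    def test_upsample_nearest(self, rng):
        x = rng.normal(0, 1, (1, 2, 3, 3)).astype(np.float32)
        check_grad(lambda t: F.upsample_nearest2d(t, 2), x)

    def test_linear_grads(self, rng):
        x0 = rng.normal(0, 1, (4, 5)).astype(np.float32)
        w0 = rng.normal(0, 0.5, (3, 5)).astype(np.float32)
        W = Tensor(w0)
        check_grad(lambda t: F.linear(t, W, None), x0)
        x = Tensor(x0)
        check_grad(lambda wt: F.linear(x, wt, None), w0)

    def test_channel_mismatch_errors(self):
        x = Tensor(np.zeros((1, 2, 4, 4), np.float32))
        W = Tensor(np.zeros((3, 5, 3, 3), np.float32))
        with pytest.raises(ValueError, match="channel"):
            F.conv2d(x, W, None)


class TestModules:
    def test_instance_norm_normalizes(self, rng):
        layer = nn.InstanceNorm2d(3)
        x = Tensor(rng.normal(3.0, 2.0, (2, 3, 8, 8)).astype(np.float32))
        y = layer(x).data
        assert np.abs(y.mean(axis=(2, 3))).max() < 1e-4
        assert np.abs(y.std(axis=(2, 3)) - 1.0).max() < 1e-2

    def test_batch_norm_train_eval(self, rng):
        layer = nn.BatchNorm2d(2)
        x = Tensor(rng.normal(1.0, 2.0, (4, 2, 8, 8)).astype(np.float32))
        y = layer(x).data
        assert np.abs(y.mean(axis=(0, 2, 3))).max() < 1e-4
        layer.eval()
        y2 = layer(x).data  # running stats barely warmed, output differs
        assert not np.allclose(y, y2)

    def test_state_dict_roundtrip(self, rng):
        net = nn.Sequential(nn.Conv2d(1, 4, 3, rng=rng), nn.BatchNorm2d(4), nn.ReLU(),
                            nn.Conv2d(4, 1, 3, rng=rng))
        x = Tensor(rng.uniform(0, 1, (1, 1, 8, 8)).astype(np.float32))
        net.eval()
        y1 = net(x).data
        state = net.state_dict()
        net2 = nn.Sequential(nn.Conv2d(1, 4, 3, rng=rng), nn.BatchNorm2d(4), nn.ReLU(),
                             nn.Conv2d(4, 1, 3, rng=rng))
        net2.load_state_dict(state)
        net2.eval()
        assert np.array_equal(net2(x).data, y1)

    def test_state_dict_mismatch_rejected(self, rng):
        net = nn.Conv2d(1, 4, 3, rng=rng)
        with pytest.raises(ValueError, match="state dict"):
            net.load_state_dict({"bogus": np.zeros(3)})

    def test_no_grad_blocks_graph(self, rng):
        x = Tensor(rng.normal(0, 1, (2, 2)).astype(np.float32), requires_grad=True)
        with no_grad():
            y = (x * 2.0).sum()
        assert not y.requires_grad


class TestAdam:
    def test_minimizes_quadratic(self):
        target = np.array([1.0, -2.0, 3.0], np.float32)
        p = Tensor(np.zeros(3, np.float32), requires_grad=True)
        opt = Adam([p], lr=0.1)
        for _ in range(300):
            opt.zero_grad()
            ((p - Tensor(target)) ** 2).sum().backward()
            opt.step()
        assert np.abs(p.data - target).max() < 1e-2

    def test_step_is_deterministic(self, rng):
        g = rng.normal(0, 1, (4,)).astype(np.float32)

        def run():
            p = Tensor(np.ones(4, np.float32), requires_grad=True)
            opt = Adam([p], lr=1e-2)
            for _ in range(10):
                opt.zero_grad()
                p.grad = g.copy()
                opt.step()
            return p.data.copy()

        assert np.array_equal(run(), run())
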