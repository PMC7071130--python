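"""Gradient correctness of every autodiff primitive vs central differences,
and forward-value checks against explicit loop oracles."""

from __future__ import annotations

import numpy as np
import pytest

from mlanet import autodiff as ad
from mlanet.autodiff import Tensor

from conftest import numeric_grad

RNG = np.random.default_rng(12345)


def check_grad(build, shapes, tol=1e-6, eps=1e-6):
    """build(*tensors) -> scalar Tensor; checks grads w.r.t. every input."""
    arrays = [RNG.standard_normal(s) for s in shapes]
    tensors = [Tensor(a.copy(), requires_grad=True) for a in arrays]
    out = build(*tensors)
    out.backward()
    for i, (a, t) in enumerate(zip(arrays, tensors)):
        def f(x, i=i):
            args = [Tensor(arr) for arr in arrays]
            args[i] = Tensor(x)
            return float(build(*args).data)
        num = numeric_grad(f, a.copy(), eps)
        assert t.grad is not None, f"input {i} got no gradient"
        np.testing.assert_allclose(t.grad, num, rtol=tol, atol=tol)


class TestElementwise:
    def test_add_mul_broadcast(self):
        check_grad(lambda a, b: (a * b + a).sum(), [(3, 4), (4,)])

    def test_sub_neg_div(self):
        check_grad(lambda a, b: ((a - b) / 3.0 - (-a)).sum(), [(2, 3), (2, 3)])

    def test_tanh_sigmoid_relu(self):
        check_grad(lambda a: (a.tanh() * a.sigmoid() + a.relu()).sum(),
                   [(5, 2)], tol=1e-5)

    def test_log_clip_min(self):
        check_grad(lambda a: (a * a + 0.5).clip_min(1e-9).log().sum(), [(6,)])

    def test_step_relu_gradient_matches_finite_differences(self):
        # avoid the kinks at 0 and 1 where the subgradient is one-sided
        x = np.array([-2.0, -0.4, 0.3, 0.5, 0.9, 1.4, 3.0])
        t = Tensor(x, requires_grad=True)
        ad.step_relu(t).sum().backward()
        num = numeric_grad(lambda a: float(ad.step_relu(Tensor(a)).sum().data), x)
        np.testing.assert_allclose(t.grad, num, atol=1e-6)


class TestMatmul:
    @pytest.mark.parametrize("sa,sb", [
        ((3, 4), (4, 5)),       # plain
        ((2, 3, 4), (4, 5)),    # batched @ parameter
        ((3, 4), (4,)),         # matrix @ vector
        ((4,), (4, 5)),         # vector @ matrix
        ((4,), (4,)),           # inner product
        ((2, 3, 4), (2, 4, 5)),  # batched both
    ])
    def test_matmul_grads(self, sa, sb):
        check_grad(lambda a, b: (a @ b).sum() if (a.data @ b.data).ndim
                   else (a @ b), [sa, sb])


class TestShaping:
    def test_reshape_transpose_getitem(self):
        check_grad(lambda a: (a.reshape(6, 2).transpose(1, 0)[:, 1:4]).sum(),
                   [(3, 4)])

    def test_concat_stack(self):
        check_grad(lambda a, b: (ad.concat([a, b], axis=1).sum()
                                 + (ad.stack([a, b], axis=0).sum(axis=0)
                                    * a).sum()),
                   [(2, 3), (2, 3)])

    def test_sum_mean_axis(self):
        check_grad(lambda a: (a.sum(axis=0) * a.mean(axis=1).sum()).sum(),
                   [(3, 4)])


class TestSoftmax:
    def test_softmax_rows_sum_to_one(self):
        x = RNG.standard_normal((7, 11))
        s = ad.softmax(Tensor(x), axis=-1).data
        assert np.all(s >= 0)
        np.testing.assert_allclose(s.sum(axis=-1), 1.0, atol=1e-12)

    def test_softmax_grad(self):
        w = RNG.standard_normal(5)
        check_grad(lambda a: (ad.softmax(a, axis=-1) @ w).sum(), [(3, 5)],
                   tol=1e-5)


class TestConv2d:
    def _loop_conv(self, x, w, b):
        """Explicit quadruple-loop SAME cross-correlation oracle."""
        B, H, W, C = x.shape
        O, _, kh, kw = w.shape
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        out = np.zeros((B, H, W, O))
        for bb in range(B):
            for i in range(H):
                for j in range(W):
                    for o in range(O):
                        acc = b[o]
                        for di in range(kh):
                            for dj in range(kw):
                                for c in range(C):
                                    acc += w[o, c, di, dj] * xp[bb, i + di, j + dj, c]
                        out[bb, i, j, o] = acc
        return out

    @pytest.mark.parametrize("kshape", [(3, 3), (5, 1), (7, 1), (1, 1)])
    def test_conv_matches_loop_oracle(self, kshape):
        kh, kw = kshape
        x = RNG.standard_normal((2, 8, 6, 3))
        w = RNG.standard_normal((4, 3, kh, kw))
        b = RNG.standard_normal(4)
        got = ad.conv2d(Tensor(x), Tensor(w), Tensor(b)).data
        np.testing.assert_allclose(got, self._loop_conv(x, w, b), atol=1e-10)

    def test_conv_grads(self):
        check_grad(lambda x, w, b: ad.conv2d(x, w, b).sum(),
                   [(2, 5, 6, 2), (3, 2, 3, 3), (3,)], tol=1e-5)

    def test_kernel_taller_than_input_rejected(self):
        with pytest.raises(ValueError):
            ad.conv2d(Tensor(np.zeros((1, 4, 4, 1))),
                      Tensor(np.zeros((1, 1, 5, 1))))


class TestMaxPool:
    def test_pool_matches_loop_oracle(self):
        x = RNG.standard_normal((2, 6, 7, 3))
        got = ad.maxpool2x2(Tensor(x)).data
        expect = np.zeros((2, 5, 6, 3))
        for b in range(2):
            for i in range(5):
                for j in range(6):
                    for c in range(3):
                        expect[b, i, j, c] = x[b, i:i + 2, j:j + 2, c].max()
        np.testing.assert_allclose(got, expect)

    def test_pool_grad(self):
        # random normal entries are distinct a.s. -> unique argmax per window
        mult = Tensor(RNG.standard_normal((1, 4, 5, 2)))
        check_grad(lambda a: (ad.maxpool2x2(a) * mult).sum(), [(1, 5, 6, 2)])

    def test_pool_tie_gradient_is_not_duplicated(self):
        x = Tensor(np.zeros((1, 3, 3, 1)), requires_grad=True)
        ad.maxpool2x2(x).sum().backward()
        # 4 windows, each routes exactly one unit of gradient
        assert x.grad.sum() == pytest.approx(4.0)

    def test_too_small_map_rejected(self):
        with pytest.raises(ValueError):
            ad.maxpool2x2(Tensor(np.zeros((1, 1, 5, 2))))


class TestBatchNorm:
    def test_batchnorm_forward_normalizes(self):
        x = RNG.standard_normal((8, 5, 3)) * 4 + 2
        g = Tensor(np.ones((1, 1, 3)))
        b = Tensor(np.zeros((1, 1, 3)))
        out, mu, var = ad.batchnorm_train(Tensor(x), g, b, (0, 1), 1e-8)
        np.testing.assert_allclose(out.data.mean(axis=(0, 1)), 0, atol=1e-10)
        np.testing.assert_allclose(out.data.std(axis=(0, 1)), 1, atol=1e-4)

    def test_batchnorm_grads(self):
        def build(x, g, b):
            out, _, _ = ad.batchnorm_train(x, g, b, (0,), 1e-3)
            return (out * out).sum()
        check_grad(build, [(6, 4), (1, 4), (1, 4)], tol=1e-5)


class TestEngine:
    def test_no_grad_suppresses_graph(self):
        x = Tensor(np.ones(3), requires_grad=True)
        with ad.no_grad():
            y = (x * 2).sum()
        assert not y.requires_grad

    def test_diamond_graph_accumulates_both_paths(self):
        x = Tensor(np.array([2.0]), requires_grad=True)
        y = x * x + x * 3.0
        y.sum().backward()
        np.testing.assert_allclose(x.grad, [7.0])  # 2x + 3

    def test_deep_chain_backward_is_iterative(self):
        # recursion-based backprop would overflow on RNN-length chains
        x = Tensor(np.ones(4), requires_grad=True)
        y = x
        for _ in range(2000):
            y = y * 1.0001
        y.sum().backward()
        assert x.grad is not None
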