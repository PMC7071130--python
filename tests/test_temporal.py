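"""Temporal branch: GRU cell semantics, bidirectional unrolling, attention."""

from __future__ import annotations

import numpy as np
import pytest

from mlanet.autodiff import Tensor
from mlanet.temporal import (GruParams, TemporalAttentionParams,
                             TemporalBranch, bigru_forward, gru_step,
                             init_gru_params, init_temporal_attention,
                             temporal_attention)

RNG = np.random.default_rng(7)


def _zero_params(d, h):
    z = lambda *s: Tensor(np.zeros(s))
    return GruParams(Wxz=z(h, d), Whz=z(h, h), Wxr=z(h, d), Whr=z(h, h),
                     Wxh=z(h, d), W=z(h, h), bz=z(h), br=z(h))


def _rand_params(rng, d, h, scale=0.6):
    r = lambda *s: Tensor(rng.standard_normal(s) * scale)
    return GruParams(Wxz=r(h, d), Whz=r(h, h), Wxr=r(h, d), Whr=r(h, h),
                     Wxh=r(h, d), W=r(h, h), bz=r(h), br=r(h))


def _scalar_gru_step(x, h_prev, p):
    """Loop-free-of-vectorization oracle for one GRU update."""
    h = len(h_prev)
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    out = np.zeros(h)
    for i in range(h):
        z = sig(p.Wxz.data[i] @ x + p.Whz.data[i] @ h_prev + p.bz.data[i])
        r_row = sig(p.Wxr.data[i] @ x + p.Whr.data[i] @ h_prev + p.br.data[i])
        # reset gate is a full vector; recompute it for the candidate
        r_full = np.array([sig(p.Wxr.data[j] @ x + p.Whr.data[j] @ h_prev
                               + p.br.data[j]) for j in range(h)])
        cand = np.tanh(p.Wxh.data[i] @ x + p.W.data[i] @ (r_full * h_prev))
        out[i] = (1 - z) * h_prev[i] + z * cand
        del r_row
    return out


class TestGruStep:
    def test_zero_params_halve_previous_state(self):
        v = RNG.standard_normal(4)
        out = gru_step(np.zeros(3), v, _zero_params(3, 4))
        # z = r = sigmoid(0) = 0.5, candidate = tanh(0) = 0
        np.testing.assert_allclose(out.data, 0.5 * v, atol=1e-12)

    def test_saturated_update_gate_returns_candidate(self):
        p = _zero_params(3, 4)
        p.bz.data[:] = 60.0   # z -> 1
        p.Wxh.data[:] = 1.0
        x = np.array([0.3, -0.1, 0.2])
        out = gru_step(x, RNG.standard_normal(4), p)
        np.testing.assert_allclose(out.data, np.tanh(np.full(4, x.sum())),
                                   atol=1e-9)

    def test_toy_matches_scalar_oracle(self):
        p = _rand_params(np.random.default_rng(2), d=3, h=2)
        x = RNG.standard_normal(3)
        h_prev = RNG.standard_normal(2)
        out = gru_step(x, h_prev, p)
        np.testing.assert_allclose(out.data, _scalar_gru_step(x, h_prev, p),
                                   atol=1e-12)

    def test_convex_combination_bound(self):
        # |h_t| <= max(|h_prev|, 1) element-wise for any params/input
        for trial in range(20):
            rng = np.random.default_rng(trial)
            p = _rand_params(rng, 5, 6, scale=2.0)
            h_prev = rng.standard_normal(6) * 3
            out = gru_step(rng.standard_normal(5), h_prev, p).data
            assert np.all(np.abs(out) <= np.maximum(np.abs(h_prev), 1.0) + 1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gru_step(np.zeros(4), np.zeros(4), _zero_params(3, 4))


class TestBigru:
    def test_output_is_t_rows_2h_columns(self):
        fwd = _rand_params(np.random.default_rng(0), 12, 5)
        bwd = _rand_params(np.random.default_rng(1), 12, 5)
        H = bigru_forward(RNG.standard_normal((12, 20)), fwd, bwd)
        assert H.shape == (20, 10)

    def test_matches_per_step_scalar_loop(self):
        fwd = _rand_params(np.random.default_rng(3), 12, 4)
        bwd = _rand_params(np.random.default_rng(4), 12, 4)
        X = RNG.standard_normal((12, 20))
        H = bigru_forward(X, fwd, bwd).data
        # forward direction oracle via repeated gru_step
        h = np.zeros(4)
        for t in range(20):
            h = gru_step(X[:, t], h, fwd).data
        np.testing.assert_allclose(H[-1, :4], h, atol=1e-10)
        h = np.zeros(4)
        for t in range(19, -1, -1):
            h = gru_step(X[:, t], h, bwd).data
        np.testing.assert_allclose(H[0, 4:], h, atol=1e-10)

    def test_time_reversal_swaps_direction_halves(self):
        fwd = _rand_params(np.random.default_rng(5), 12, 3)
        X = RNG.standard_normal((12, 15))
        # share params across directions so reversal is an exact symmetry
        H = bigru_forward(X, fwd, fwd).data
        Hr = bigru_forward(X[:, ::-1], fwd, fwd).data
        np.testing.assert_allclose(Hr[::-1, :3], H[:, 3:], atol=1e-10)
        np.testing.assert_allclose(Hr[::-1, 3:], H[:, :3], atol=1e-10)

    def test_zero_input_zero_params_zero_states(self):
        p = _zero_params(12, 4)
        H = bigru_forward(np.zeros((12, 8)), p, p).data
        np.testing.assert_array_equal(H, 0.0)

    def test_wrong_input_width_rejected(self):
        p = _rand_params(np.random.default_rng(0), 12, 3)
        with pytest.raises(ValueError):
            bigru_forward(np.zeros((11, 20)), p, p)

    def test_batched_equals_per_sample(self):
        fwd = _rand_params(np.random.default_rng(8), 12, 4)
        bwd = _rand_params(np.random.default_rng(9), 12, 4)
        X = RNG.standard_normal((3, 12, 20))
        Hb = bigru_forward(X, fwd, bwd).data
        for b in range(3):
            np.testing.assert_allclose(
                Hb[b], bigru_forward(X[b], fwd, bwd).data, atol=1e-5)


class TestTemporalAttention:
    def test_identical_rows_uniform_weights(self):
        params = init_temporal_attention(np.random.default_rng(0), d=6, a=4,
                                         dtype=np.float64)
        H = np.tile(RNG.standard_normal(6), (9, 1))
        ft, alpha = temporal_attention(H, params)
        np.testing.assert_allclose(alpha.data, 1.0 / 9, atol=1e-12)
        np.testing.assert_allclose(ft.data, H[0], atol=1e-10)

    def test_singleton_time_axis(self):
        params = init_temporal_attention(np.random.default_rng(1), d=6, a=4,
                                         dtype=np.float64)
        H = RNG.standard_normal((1, 6))
        ft, alpha = temporal_attention(H, params)
        np.testing.assert_allclose(alpha.data, [1.0])
        np.testing.assert_allclose(ft.data, H[0], atol=1e-12)

    def test_toy_matches_scalar_oracle(self):
        rng = np.random.default_rng(6)
        W3 = rng.standard_normal((4, 2))
        b3 = rng.standard_normal(4)
        w3 = rng.standard_normal(4)
        H = rng.standard_normal((3, 2))
        ft, alpha = temporal_attention(
            H, TemporalAttentionParams(Tensor(W3), Tensor(b3), Tensor(w3)))
        scores = np.array([w3 @ np.tanh(W3 @ H[t] + b3) for t in range(3)])
        e = np.exp(scores - scores.max())
        ae = e / e.sum()
        np.testing.assert_allclose(alpha.data, ae, atol=1e-12)
        np.testing.assert_allclose(ft.data, (ae[:, None] * H).sum(0), atol=1e-12)

    def test_normalization_over_random_draws(self):
        for trial in range(100):
            rng = np.random.default_rng(1000 + trial)
            params = init_temporal_attention(rng, d=6, a=3, dtype=np.float64)
            _, alpha = temporal_attention(rng.standard_normal((4, 11, 6)),
                                          params)
            assert np.all(alpha.data >= 0)
            np.testing.assert_allclose(alpha.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_mismatched_width_rejected(self):
        params = init_temporal_attention(np.random.default_rng(0), d=6, a=3)
        with pytest.raises(ValueError):
            temporal_attention(np.zeros((5, 7)), params)


def test_branch_output_width_is_twice_hidden():
    branch = TemporalBranch(np.random.default_rng(0), hidden_size=5, att_dim=4)
    ft, alpha = branch.forward(RNG.standard_normal((2, 12, 30)).astype(np.float32))
    assert ft.shape == (2, 10)
    assert alpha.shape == (2, 30)
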