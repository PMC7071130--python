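"""Temporal branch: bidirectional GRU over the 651 time steps + attention.

Each time step feeds the 12-lead sample x_t into a GRU cell:

    z_t = sigma(Wxz x_t + Whz h_{t-1} + bz)         update gate
    r_t = sigma(Wxr x_t + Whr h_{t-1} + br)         reset gate
    h~_t = tanh(Wxh x_t + W (r_t * h_{t-1}))        candidate state
    h_t = (1 - z_t) * h_{t-1} + z_t * h~_t

The candidate line carries no bias by default (an optional ``bh`` can be
enabled); the two directions use independent parameter sets and their hidden
states are concatenated per step into H (T x 2h).  After batch norm and
dropout, a softmax attention pools H into the temporal feature ``ft``:

    alpha3 = softmax(w3' tanh(W3 H^T + b3)),   ft = sum_t alpha3_t H_t
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor, concat, softmax, stack
from .nnlayers import BatchNorm, dropout, glorot_uniform


@dataclasses.dataclass
class GruParams:
    Wxz: Tensor  # (h, d_in)
    Whz: Tensor  # (h, h)
    Wxr: Tensor  # (h, d_in)
    Whr: Tensor  # (h, h)
    Wxh: Tensor  # (h, d_in)
    W: Tensor    # (h, h) — recurrent weight of the candidate state
    bz: Tensor   # (h,)
    br: Tensor   # (h,)
    bh: Tensor | None = None  # optional candidate bias (off by default)

    @property
    def hidden_size(self) -> int:
        return self.Whz.shape[0]

    @property
    def input_size(self) -> int:
        return self.Wxz.shape[1]

    def tensors(self):
        out = [self.Wxz, self.Whz, self.Wxr, self.Whr, self.Wxh, self.W,
               self.bz, self.br]
        if self.bh is not None:
            out.append(self.bh)
        return out


def init_gru_params(rng: np.random.Generator, input_size: int = 12,
                    hidden_size: int = 64, candidate_bias: bool = False,
                    dtype=np.float32) -> GruParams:
    h, d = hidden_size, input_size

    def wx():
        return glorot_uniform(rng, (h, d), d, h, dtype)

    def wh():
        # scaled orthogonal-ish recurrent init
        q, _ = np.linalg.qr(rng.standard_normal((h, h)))
        return Tensor(q.astype(dtype), requires_grad=True)

    zeros = lambda: Tensor(np.zeros(h, dtype=dtype), requires_grad=True)
    return GruParams(
        Wxz=wx(), Whz=wh(), Wxr=wx(), Whr=wh(), Wxh=wx(), W=wh(),
        bz=zeros(), br=zeros(),
        bh=zeros() if candidate_bias else None,
    )


def gru_step(xt, h_prev, params: GruParams) -> Tensor:
    """One GRU update; xt (d,) or (B, d), h_prev (h,) or (B, h)."""
    if not isinstance(xt, Tensor):
        xt = Tensor(np.asarray(xt, dtype=params.Wxz.data.dtype))
    if not isinstance(h_prev, Tensor):
        h_prev = Tensor(np.asarray(h_prev, dtype=params.Wxz.data.dtype))
    if xt.shape[-1] != params.input_size or h_prev.shape[-1] != params.hidden_size:
        raise ValueError(
            f"shape mismatch: xt {xt.shape}, h_prev {h_prev.shape} vs "
            f"(d={params.input_size}, h={params.hidden_size})")
    WxzT = params.Wxz.transpose(1, 0)
    WhzT = params.Whz.transpose(1, 0)
    WxrT = params.Wxr.transpose(1, 0)
    WhrT = params.Whr.transpose(1, 0)
    WxhT = params.Wxh.transpose(1, 0)
    WT = params.W.transpose(1, 0)
    z = (xt @ WxzT + h_prev @ WhzT + params.bz).sigmoid()
    r = (xt @ WxrT + h_prev @ WhrT + params.br).sigmoid()
    cand = xt @ WxhT + (r * h_prev) @ WT
    if params.bh is not None:
        cand = cand + params.bh
    h_tilde = cand.tanh()
    return (1.0 - z) * h_prev + z * h_tilde


def _unroll(Xt: Tensor, params: GruParams, reverse: bool) -> list:
    """Run one direction over Xt (B, T, d); returns T hidden states (B, h)."""
    B, T, _ = Xt.shape
    h = params.hidden_size
    dtype = params.Wxz.data.dtype
    # project all inputs through the three input matrices in one shot
    xz = Xt @ params.Wxz.transpose(1, 0)
    xr = Xt @ params.Wxr.transpose(1, 0)
    xh = Xt @ params.Wxh.transpose(1, 0)
    WhzT = params.Whz.transpose(1, 0)
    WhrT = params.Whr.transpose(1, 0)
    WT = params.W.transpose(1, 0)
    ht = Tensor(np.zeros((B, h), dtype=dtype))
    order = range(T - 1, -1, -1) if reverse else range(T)
    states: list = [None] * T
    for t in order:
        z = (xz[:, t, :] + ht @ WhzT + params.bz).sigmoid()
        r = (xr[:, t, :] + ht @ WhrT + params.br).sigmoid()
        cand = xh[:, t, :] + (r * ht) @ WT
        if params.bh is not None:
            cand = cand + params.bh
        ht = (1.0 - z) * ht + z * cand.tanh()
        states[t] = ht
    return states


def bigru_forward(X, fwd: GruParams, bwd: GruParams) -> Tensor:
    """Bidirectional pass over a beat (12 x T) or batch (B x 12 x T).

    Time steps are the columns of X; returns H of shape (T, 2h) or
    (B, T, 2h) with the forward and backward states concatenated per step.
    Initial hidden states are zero.
    """
    if fwd.hidden_size != bwd.hidden_size:
        raise ValueError("both directions must share the hidden size")
    if not isinstance(X, Tensor):
        X = Tensor(np.asarray(X, dtype=fwd.Wxz.data.dtype))
    squeeze = X.ndim == 2
    if squeeze:
        X = X.reshape(1, X.shape[0], X.shape[1])
    if X.shape[1] != fwd.input_size:
        raise ValueError(
            f"input has {X.shape[1]} rows; GRU expects {fwd.input_size}")
    Xt = X.transpose(0, 2, 1)  # (B, T, d)
    f_states = _unroll(Xt, fwd, reverse=False)
    b_states = _unroll(Xt, bwd, reverse=True)
    Hf = stack(f_states, axis=1)   # (B, T, h)
    Hb = stack(b_states, axis=1)
    H = concat([Hf, Hb], axis=2)   # (B, T, 2h)
    if squeeze:
        H = H.reshape(H.shape[1], H.shape[2])
    return H


@dataclasses.dataclass
class TemporalAttentionParams:
    W3: Tensor  # (a, 2h)
    b3: Tensor  # (a,)
    w3: Tensor  # (a,)

    def tensors(self):
        return [self.W3, self.b3, self.w3]


def init_temporal_attention(rng: np.random.Generator, d: int, a: int = 64,
                            dtype=np.float32) -> TemporalAttentionParams:
    return TemporalAttentionParams(
        W3=glorot_uniform(rng, (a, d), d, a, dtype),
        b3=Tensor(np.zeros(a, dtype=dtype), requires_grad=True),
        w3=glorot_uniform(rng, (a,), a, 1, dtype),
    )


def temporal_attention(H, params: TemporalAttentionParams):
    """Pool hidden states (T x 2h, or batched) into ft; returns (ft, alpha3)."""
    if not isinstance(H, Tensor):
        H = Tensor(np.asarray(H, dtype=params.W3.data.dtype))
    if H.shape[-1] != params.W3.shape[1]:
        raise ValueError(
            f"hidden states of width {H.shape[-1]} do not match "
            f"W3 {params.W3.shape}")
    scores = (H @ params.W3.transpose(1, 0) + params.b3).tanh() @ params.w3
    alpha3 = softmax(scores, axis=-1)
    ft = (alpha3[..., None] * H).sum(axis=-2)
    return ft, alpha3


class TemporalBranch:
    """BiGRU -> BN -> dropout -> temporal attention."""

    def __init__(self, rng: np.random.Generator, n_leads: int = 12,
                 hidden_size: int = 64, att_dim: int = 64,
                 dropout_rate: float = 0.3, candidate_bias: bool = False,
                 bn_momentum: float = 0.99, bn_eps: float = 1e-3,
                 dtype=np.float32):
        self.fwd = init_gru_params(rng, n_leads, hidden_size, candidate_bias, dtype)
        self.bwd = init_gru_params(rng, n_leads, hidden_size, candidate_bias, dtype)
        self.bn = BatchNorm(2 * hidden_size, 3, 2, bn_momentum, bn_eps, dtype)
        self.attention = init_temporal_attention(rng, 2 * hidden_size, att_dim, dtype)
        self.dropout_rate = dropout_rate
        self.out_len = 2 * hidden_size

    def forward(self, X, training: bool = False,
                rng: np.random.Generator | None = None):
        """X: (B, 12, T) -> (ft (B, 2h), alpha3 (B, T))."""
        H = bigru_forward(X, self.fwd, self.bwd)
        H = self.bn(H, training)
        H = dropout(H, self.dropout_rate, training, rng)
        return temporal_attention(H, self.attention)

    def tensors(self):
        return (self.fwd.tensors() + self.bwd.tensors()
                + self.bn.tensors() + self.attention.tensors())
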