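"""Spatial branch: 2D-CNN over the lead x time plane with feature attention.

Two conv-BN-pool-dropout stages, each convolving with three kernel shapes in
parallel — (3,3), (5,1) and (7,1), 20 kernels per shape by default — whose
SAME-padded outputs are concatenated on the channel axis (60 maps/stage).
The tall 5x1 / 7x1 kernels mix five or seven *leads* at a single time point,
which is where cross-lead correlation enters.  Max pooling uses a (2,2)
window with stride 1, so each spatial dimension shrinks by exactly one per
stage.  The 60 final maps are flattened into vectors and combined by a
softmax attention layer into the spatial feature ``fs``:

    alpha2 = softmax(w2' tanh(W2 X'^T + b2)),   fs = sum_n alpha2_n x'_n
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor, concat, conv2d, maxpool2x2, softmax
from .nnlayers import BatchNorm, dropout, glorot_uniform

KERNEL_SHAPES: tuple[tuple[int, int], ...] = ((3, 3), (5, 1), (7, 1))


@dataclasses.dataclass
class ConvLayerParams:
    """Parallel kernel groups for one conv layer: [(W, b), ...] per shape."""

    groups: list  # [(weights (O,C,kh,kw) Tensor, bias (O,) Tensor), ...]
    shapes: tuple = KERNEL_SHAPES

    @property
    def n_channels(self) -> int:
        return sum(w.shape[0] for w, _ in self.groups)

    def tensors(self):
        out = []
        for w, b in self.groups:
            out.extend([w, b])
        return out


def init_conv_layer(rng: np.random.Generator, in_channels: int,
                    n_per_shape: int = 20, shapes=KERNEL_SHAPES,
                    dtype=np.float32) -> ConvLayerParams:
    groups = []
    for kh, kw in shapes:
        fan_in = in_channels * kh * kw
        w = glorot_uniform(rng, (n_per_shape, in_channels, kh, kw),
                           fan_in, n_per_shape, dtype)
        b = Tensor(np.zeros(n_per_shape, dtype=dtype), requires_grad=True)
        groups.append((w, b))
    return ConvLayerParams(groups, tuple(shapes))


def conv_layer(x, params: ConvLayerParams) -> Tensor:
    """SAME conv (stride 1) with every kernel group + ReLU, concatenated.

    Channels-last: x is (B, H, W, C); returns (B, H, W, sum(O_g)).
    """
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x))
    outs = [conv2d(x, w, b).relu() for w, b in params.groups]
    return outs[0] if len(outs) == 1 else concat(outs, axis=3)


def max_pool(maps, window: tuple = (2, 2), stride: int = 1) -> Tensor:
    """Valid max pooling; only the (2,2)/stride-1 configuration is supported."""
    if tuple(window) != (2, 2) or stride != 1:
        raise ValueError("only a (2,2) window with stride 1 is supported")
    if not isinstance(maps, Tensor):
        maps = Tensor(np.asarray(maps))
    return maxpool2x2(maps)


@dataclasses.dataclass
class FeatureAttentionParams:
    W2: Tensor  # (a, d)
    b2: Tensor  # (a,)
    w2: Tensor  # (a,)

    def tensors(self):
        return [self.W2, self.b2, self.w2]


def init_feature_attention(rng: np.random.Generator, d: int, a: int = 64,
                           dtype=np.float32) -> FeatureAttentionParams:
    return FeatureAttentionParams(
        W2=glorot_uniform(rng, (a, d), d, a, dtype),
        b2=Tensor(np.zeros(a, dtype=dtype), requires_grad=True),
        w2=glorot_uniform(rng, (a,), a, 1, dtype),
    )


def feature_attention(xprime, params: FeatureAttentionParams):
    """Softmax-weighted combination of the N flattened feature maps.

    xprime: (N, d) or (B, N, d).  Returns (fs, alpha2) with fs of length d
    and alpha2 non-negative summing to one.
    """
    if not isinstance(xprime, Tensor):
        xprime = Tensor(np.asarray(xprime, dtype=params.W2.data.dtype))
    if xprime.shape[-1] != params.W2.shape[1]:
        raise ValueError(
            f"feature vectors of length {xprime.shape[-1]} do not match "
            f"W2 {params.W2.shape}")
    scores = (xprime @ params.W2.transpose(1, 0) + params.b2).tanh() @ params.w2
    alpha2 = softmax(scores, axis=-1)            # (..., N)
    fs = (alpha2[..., None] * xprime).sum(axis=-2)
    return fs, alpha2


class SpatialBranch:
    """conv->ReLU->BN->maxpool->dropout, twice, then feature attention."""

    def __init__(self, rng: np.random.Generator, n_leads: int = 12,
                 n_samples: int = 651, n_per_shape: int = 20,
                 att_dim: int = 64, dropout_rate: float = 0.3,
                 bn_momentum: float = 0.99, bn_eps: float = 1e-3,
                 dtype=np.float32):
        n_ch = n_per_shape * len(KERNEL_SHAPES)
        self.conv1 = init_conv_layer(rng, 1, n_per_shape, dtype=dtype)
        self.conv2 = init_conv_layer(rng, n_ch, n_per_shape, dtype=dtype)
        self.bn1 = BatchNorm(n_ch, 4, 3, bn_momentum, bn_eps, dtype)
        self.bn2 = BatchNorm(n_ch, 4, 3, bn_momentum, bn_eps, dtype)
        self.out_len = (n_leads - 2) * (n_samples - 2)
        self.attention = init_feature_attention(rng, self.out_len, att_dim, dtype)
        self.dropout_rate = dropout_rate
        self.n_channels = n_ch

    def forward(self, X, training: bool = False,
                rng: np.random.Generator | None = None):
        """X: (B, 12, 651) -> (fs (B, d), alpha2 (B, 60))."""
        if not isinstance(X, Tensor):
            X = Tensor(np.asarray(X))
        B = X.shape[0]
        h = X.reshape(B, X.shape[1], X.shape[2], 1)  # channels-last plane
        for conv, bn in ((self.conv1, self.bn1), (self.conv2, self.bn2)):
            h = conv_layer(h, conv)
            h = bn(h, training)
            h = maxpool2x2(h)
            h = dropout(h, self.dropout_rate, training, rng)
        B_, H, W, C = h.shape
        # one map per channel, flattened row-major into a feature vector
        xprime = h.transpose(0, 3, 1, 2).reshape(B_, C, H * W)
        return feature_attention(xprime, self.attention)

    def tensors(self):
        return (self.conv1.tensors() + self.conv2.tensors()
                + self.bn1.tensors() + self.bn2.tensors()
                + self.attention.tensors())
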