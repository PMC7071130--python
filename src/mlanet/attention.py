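"""Multi-lead attention (MLA): per-lead soft selection via StepReLU.

The mechanism scores each of the k=12 leads from the beat matrix L (k x t):

    M1     = tanh(W1 L + b1)          W1: k x k, b1: k (added to every column)
    alpha1 = StepReLU(M1 w1)          w1: t
    X      = alpha1 (x) L             row i of X = alpha1[i] * row i of L

StepReLU clips to [0, 1]: a weight of exactly 0 eliminates a lead, 1 keeps
it entirely, intermediate values pass a scaled copy.  Unlike softmax
attention the weights are not forced to compete, so any subset of leads can
be retained at full strength.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor, step_relu, step_relu_grad  # noqa: F401 - re-exported

__all__ = ["MlaParams", "step_relu", "step_relu_grad", "mla_forward",
           "init_mla_params"]


@dataclasses.dataclass
class MlaParams:
    W1: Tensor  # (k, k)
    b1: Tensor  # (k,)
    w1: Tensor  # (t,)

    def __post_init__(self):
        k = self.W1.shape[0]
        if self.W1.shape != (k, k):
            raise ValueError("W1 must be square (k x k)")
        if self.b1.shape != (k,):
            raise ValueError("b1 must be a k-vector")
        if self.w1.ndim != 1:
            raise ValueError("w1 must be a t-vector")

    def tensors(self):
        return [self.W1, self.b1, self.w1]


def init_mla_params(rng: np.random.Generator, k: int = 12, t: int = 651,
                    dtype=np.float32) -> MlaParams:
    """Near-uniform initial attention: every lead starts with the same
    mid-branch weight and a live gradient.

    W1 is a damped Glorot draw and w1 a small positive uniform, with
    b1 = 0.1, so the initial scores M1 w1 sit near 0.5 — inside StepReLU's
    identity branch — with only a small spread across leads.  Two reasons:
    a zero-mean score init would park roughly half the leads on the dead
    branch from the first step, and a large initial spread would encode an
    arbitrary lead ranking that short trainings cannot wash out (reported
    lead weights should reflect training, not the draw).
    """
    lim = 0.2 * np.sqrt(6.0 / (k + k))
    W1 = Tensor(rng.uniform(-lim, lim, (k, k)).astype(dtype), requires_grad=True)
    b1 = Tensor(np.full(k, 0.1, dtype=dtype), requires_grad=True)
    w1 = Tensor(rng.uniform(0.0, 10.0 / t, t).astype(dtype),
                requires_grad=True)
    return MlaParams(W1, b1, w1)


def _step_relu_straight_through(x: Tensor) -> Tensor:
    """Clip to [0,1] forward; pass the gradient through unchanged."""
    def backward():
        if x.requires_grad:
            x._accum(out.grad)

    out = Tensor._make(np.clip(x.data, 0.0, 1.0), (x,), backward)
    return out


def mla_forward(L, params: MlaParams, straight_through: bool = False):
    """Apply MLA to a beat (k x t) or a batch (B x k x t).

    Returns ``(X, alpha1)`` where X has L's shape and alpha1 is the per-lead
    weight vector (k, or B x k), every entry in [0, 1].
    """
    if not isinstance(L, Tensor):
        L = Tensor(np.asarray(L, dtype=params.W1.data.dtype))
    k = params.W1.shape[0]
    if L.shape[-2] != k or L.shape[-1] != params.w1.shape[0]:
        raise ValueError(
            f"beat shape {L.shape} does not match params "
            f"(k={k}, t={params.w1.shape[0]})")
    M1 = (params.W1 @ L + params.b1.reshape(k, 1)).tanh()
    scores = M1 @ params.w1                      # (..., k)
    act = _step_relu_straight_through if straight_through else step_relu
    alpha1 = act(scores)
    X = alpha1[..., None] * L
    return X, alpha1
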