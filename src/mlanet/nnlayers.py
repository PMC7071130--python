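"""Shared neural-network plumbing: batch norm, dropout, initializers."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, batchnorm_train


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out,
                   dtype=np.float32) -> Tensor:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, shape).astype(dtype), requires_grad=True)


class BatchNorm:
    """Batch normalization over all axes except ``channel_axis``.

    Training mode normalizes with batch statistics and updates exponential
    running averages; eval mode uses the running statistics.
    """

    def __init__(self, num_features: int, ndim: int, channel_axis: int,
                 momentum: float = 0.99, eps: float = 1e-3,
                 dtype=np.float32):
        shape = [1] * ndim
        shape[channel_axis] = num_features
        self.shape = tuple(shape)
        self.axes = tuple(i for i in range(ndim) if i != channel_axis)
        self.gamma = Tensor(np.ones(self.shape, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(self.shape, dtype=dtype), requires_grad=True)
        # zero-debiased exponential moving averages (see eval path)
        self.running_mean = np.zeros(self.shape, dtype=dtype)
        self.running_var = np.zeros(self.shape, dtype=dtype)
        self.n_updates = 0  # -1 marks exact (recalibrated) statistics
        self.momentum = momentum
        self.eps = eps
        self._calib: list | None = None

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            out, mu, var = batchnorm_train(x, self.gamma, self.beta,
                                           self.axes, self.eps)
            if self._calib is not None:
                self._calib[0] += mu.reshape(self.shape)
                self._calib[1] += var.reshape(self.shape)
                self._calib[2] += 1
                return out
            m = self.momentum
            if self.n_updates < 0:  # resuming after a recalibration
                self.n_updates = 0
                self.running_mean = np.zeros_like(self.running_mean)
                self.running_var = np.zeros_like(self.running_var)
            self.running_mean = (m * self.running_mean
                                 + (1 - m) * mu.reshape(self.shape))
            self.running_var = (m * self.running_var
                                + (1 - m) * var.reshape(self.shape))
            self.n_updates += 1
            return out
        # evaluation statistics: exact after recalibration, otherwise the
        # zero-debiased EMA so short trainings still get usable values
        if self.n_updates == 0:
            rm = np.zeros(self.shape, dtype=x.data.dtype)
            rv = np.ones(self.shape, dtype=x.data.dtype)
        elif self.n_updates < 0:
            rm, rv = self.running_mean, self.running_var
        else:
            corr = 1.0 - self.momentum ** self.n_updates
            rm = self.running_mean / corr
            rv = self.running_var / corr
        istd = 1.0 / np.sqrt(rv + self.eps)
        return self.gamma * ((x + Tensor(-rm)) * Tensor(istd)) + self.beta

    def begin_calibration(self) -> None:
        self._calib = [np.zeros(self.shape), np.zeros(self.shape), 0]

    def end_calibration(self) -> None:
        s_mu, s_var, n = self._calib
        self._calib = None
        if n == 0:
            return
        self.running_mean = (s_mu / n).astype(self.running_mean.dtype)
        self.running_var = (s_var / n).astype(self.running_var.dtype)
        self.n_updates = -1

    def tensors(self):
        return [self.gamma, self.beta]

    def state(self, prefix: str) -> dict:
        return {f"{prefix}.running_mean": self.running_mean,
                f"{prefix}.running_var": self.running_var,
                f"{prefix}.n_updates": np.array(self.n_updates)}

    def load_state(self, prefix: str, arrays: dict) -> None:
        self.running_mean = arrays[f"{prefix}.running_mean"]
        self.running_var = arrays[f"{prefix}.running_var"]
        self.n_updates = int(arrays[f"{prefix}.n_updates"])


def dropout(x: Tensor, rate: float, training: bool,
            rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    if rng is None:
        raise ValueError("dropout in training mode requires an RNG")
    mask = (rng.random(x.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)
    return x * Tensor(mask)
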