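"""The assembled MLA-CNN-BiGRU network: fusion and classification head.

A beat batch (B x 12 x 651) passes through multi-lead attention, then in
parallel through the spatial CNN branch (-> fs) and the temporal BiGRU
branch (-> ft).  The two features are concatenated, F = [fs, ft], batch
normalized, dropped out, and classified by a single fully connected layer —
sigmoid for detection (MI vs HC) or softmax over classes for localization.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .attention import init_mla_params, mla_forward
from .autodiff import Tensor, concat, softmax
from .nnlayers import BatchNorm, dropout, glorot_uniform
from .spatial import SpatialBranch
from .temporal import TemporalBranch


@dataclasses.dataclass
class ModelConfig:
    task: str = "detection"            # "detection" or "location"
    class_names: tuple = ("HC", "MI")  # positive class last for detection
    n_leads: int = 12
    n_samples: int = 651
    n_kernels_per_shape: int = 20
    gru_hidden: int = 64
    att_dim: int = 64
    dropout: float = 0.3
    bn_momentum: float = 0.99
    bn_eps: float = 1e-3
    straight_through_mla: bool = False
    gru_candidate_bias: bool = False
    dtype: str = "float32"

    def __post_init__(self):
        self.class_names = tuple(self.class_names)
        if self.task not in ("detection", "location"):
            raise ValueError("task must be 'detection' or 'location'")
        if self.task == "detection" and len(self.class_names) != 2:
            raise ValueError("detection requires exactly two classes")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    @property
    def n_outputs(self) -> int:
        return 1 if self.task == "detection" else len(self.class_names)


class MlaCnnBigru:
    """Full model: parameters, forward pass, and (de)serialization."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        ad.tune_allocator()
        self.config = config
        rng = np.random.default_rng(seed)
        dt = config.np_dtype
        self.mla = init_mla_params(rng, config.n_leads, config.n_samples, dt)
        self.spatial = SpatialBranch(
            rng, config.n_leads, config.n_samples, config.n_kernels_per_shape,
            config.att_dim, config.dropout, config.bn_momentum, config.bn_eps, dt)
        self.temporal = TemporalBranch(
            rng, config.n_leads, config.gru_hidden, config.att_dim,
            config.dropout, config.gru_candidate_bias,
            config.bn_momentum, config.bn_eps, dt)
        fused = self.spatial.out_len + self.temporal.out_len
        self.bn_fuse = BatchNorm(fused, 2, 1, config.bn_momentum,
                                 config.bn_eps, dt)
        self.Wc = glorot_uniform(rng, (config.n_outputs, fused), fused,
                                 config.n_outputs, dt)
        self.bc = Tensor(np.zeros(config.n_outputs, dtype=dt),
                         requires_grad=True)

    # -- forward --------------------------------------------------------------
    def forward(self, batch, training: bool = False,
                rng: np.random.Generator | None = None):
        """Returns (probs Tensor, diagnostics dict with alpha1/2/3 arrays).

        probs is (B,) in (0,1) for detection, (B, C) rows summing to 1 for
        localization.
        """
        X = np.asarray(batch, dtype=self.config.np_dtype)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != (self.config.n_leads, self.config.n_samples):
            raise ValueError(
                f"batch must be B x {self.config.n_leads} x "
                f"{self.config.n_samples}, got {X.shape}")
        Xw, alpha1 = mla_forward(Tensor(X), self.mla,
                                 self.config.straight_through_mla)
        fs, alpha2 = self.spatial.forward(Xw, training, rng)
        ft, alpha3 = self.temporal.forward(Xw, training, rng)
        F = concat([fs, ft], axis=1)
        F = self.bn_fuse(F, training)
        F = dropout(F, self.config.dropout, training, rng)
        logits = F @ self.Wc.transpose(1, 0) + self.bc
        if self.config.task == "detection":
            probs = logits.reshape(logits.shape[0]).sigmoid()
        else:
            probs = softmax(logits, axis=-1)
        diag = {"alpha1": alpha1.data, "alpha2": alpha2.data,
                "alpha3": alpha3.data}
        return probs, diag

    def predict(self, beats, batch_size: int = 32):
        """Class indices and probabilities for an array of beats (no grad)."""
        X = np.asarray(beats, dtype=self.config.np_dtype)
        if X.ndim == 2:
            X = X[None]
        probs_all, alpha1_all = [], []
        with ad.no_grad():
            for lo in range(0, X.shape[0], batch_size):
                probs, diag = self.forward(X[lo:lo + batch_size], training=False)
                probs_all.append(probs.data)
                alpha1_all.append(diag["alpha1"])
        probs = np.concatenate(probs_all)
        alpha1 = np.concatenate(alpha1_all)
        if self.config.task == "detection":
            pred = (probs >= 0.5).astype(int)
        else:
            pred = probs.argmax(axis=1)
        return pred, probs, alpha1

    def recalibrate_batchnorm(self, beats, batch_size: int = 32) -> None:
        """Replace BN evaluation statistics with exact population moments.

        Runs the final model over ``beats`` in batch-statistics mode (no
        dropout, no parameter updates) and averages the per-batch moments.
        Exponential averages collected *during* training describe a mixture
        of past models; when the network changes quickly — e.g. the MLA
        eliminating leads late in a short run — those lag badly and eval
        predictions diverge from training behaviour.
        """
        sites = [bn for _, bn in self._bn_sites()]
        rates = (self.config.dropout, self.spatial.dropout_rate,
                 self.temporal.dropout_rate)
        self.config.dropout = 0.0
        self.spatial.dropout_rate = 0.0
        self.temporal.dropout_rate = 0.0
        for bn in sites:
            bn.begin_calibration()
        try:
            X = np.asarray(beats, dtype=self.config.np_dtype)
            with ad.no_grad():
                for lo in range(0, X.shape[0], batch_size):
                    self.forward(X[lo:lo + batch_size], training=True)
        finally:
            for bn in sites:
                bn.end_calibration()
            (self.config.dropout, self.spatial.dropout_rate,
             self.temporal.dropout_rate) = rates

    # -- parameter access -----------------------------------------------------
    def parameters(self) -> list:
        return (self.mla.tensors() + self.spatial.tensors()
                + self.temporal.tensors() + self.bn_fuse.tensors()
                + [self.Wc, self.bc])

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialization --------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        for name, bn in self._bn_sites():
            arrays.update(bn.state(name))
        arrays["config_json"] = np.array(
            json.dumps(dataclasses.asdict(self.config)))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MlaCnnBigru":
        with np.load(Path(path) if str(path).endswith(".npz")
                     else Path(str(path) + ".npz"), allow_pickle=False) as z:
            cfg_dict = json.loads(str(z["config_json"]))
            cfg_dict["class_names"] = tuple(cfg_dict["class_names"])
            model = cls(ModelConfig(**cfg_dict), seed=0)
            for i, p in enumerate(model.parameters()):
                p.data = z[f"param_{i}"].copy()
            arrays = {k: z[k].copy() for k in z.files}
        for name, bn in model._bn_sites():
            bn.load_state(name, arrays)
        return model

    def _bn_sites(self):
        return [("bn1", self.spatial.bn1), ("bn2", self.spatial.bn2),
                ("bn_t", self.temporal.bn), ("bn_f", self.bn_fuse)]


def fuse_and_classify(fs, ft, model: MlaCnnBigru, training: bool = False,
                      rng: np.random.Generator | None = None) -> Tensor:
    """Classification head alone: concat -> BN -> dropout -> FC -> prob."""
    if not isinstance(fs, Tensor):
        fs = Tensor(np.asarray(fs, dtype=model.config.np_dtype))
    if not isinstance(ft, Tensor):
        ft = Tensor(np.asarray(ft, dtype=model.config.np_dtype))
    if fs.ndim == 1:
        fs = fs.reshape(1, fs.shape[0])
    if ft.ndim == 1:
        ft = ft.reshape(1, ft.shape[0])
    F = concat([fs, ft], axis=1)
    if F.shape[1] != model.Wc.shape[1]:
        raise ValueError(
            f"fused feature length {F.shape[1]} does not match classifier "
            f"input {model.Wc.shape[1]}")
    F = model.bn_fuse(F, training)
    F = dropout(F, model.config.dropout, training, rng)
    logits = F @ model.Wc.transpose(1, 0) + model.bc
    if model.config.task == "detection":
        return logits.reshape(logits.shape[0]).sigmoid()
    return softmax(logits, axis=-1)
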