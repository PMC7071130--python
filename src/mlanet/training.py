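"""Training loop: cross-entropy losses, Adam, mini-batching, grid search.

Each epoch shuffles the training beats once (seeded), slices them into
consecutive batches, and minimizes the mean cross-entropy with Adam
(beta1=0.9, beta2=0.999, eps=1e-7).  The final-epoch model is returned —
there is no early stopping; the validation split exists for hyperparameter
selection.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .io import BeatDataset
from .model import MlaCnnBigru, ModelConfig


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 24
    learning_rate: float = 0.001
    epochs: int = 20
    dropout: float = 0.3
    seed: int = 0
    task: str = "detection"
    class_names: tuple = ("HC", "MI")

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        self.class_names = tuple(self.class_names)


def loss(probs, labels, task: str = "detection"):
    """Mean cross-entropy of predicted probabilities over a batch.

    detection: probs (B,) sigmoid outputs, labels in {0,1}.
    location:  probs (B,C) softmax rows, labels one-hot (B,C) or class ints.
    Returns a scalar Tensor (differentiable if probs is on the tape).
    """
    if not isinstance(probs, Tensor):
        probs = Tensor(np.asarray(probs, dtype=float))
    labels = np.asarray(labels)
    eps = 1e-12
    if task == "detection":
        y = labels.astype(float)
        if y.shape != probs.shape:
            raise ValueError(f"labels {y.shape} do not match probs {probs.shape}")
        if np.any((y != 0) & (y != 1)):
            raise ValueError("detection labels must be 0 or 1")
        yt = Tensor(y)
        ll = yt * probs.clip_min(eps).log() \
            + (1.0 - yt) * (1.0 - probs).clip_min(eps).log()
        return -ll.mean()
    if task == "location":
        n_classes = probs.shape[-1]
        if labels.ndim == 1:  # integer labels -> one-hot
            if np.any((labels < 0) | (labels >= n_classes)):
                raise ValueError("label outside the class set")
            onehot = np.eye(n_classes)[labels.astype(int)]
        else:
            onehot = labels.astype(float)
            if onehot.shape != probs.shape:
                raise ValueError(
                    f"one-hot labels {onehot.shape} do not match probs "
                    f"{probs.shape}")
        ce = -(Tensor(onehot) * probs.clip_min(eps).log()).sum(axis=-1)
        return ce.mean()
    raise ValueError(f"unknown task: {task!r}")


class Adam:
    def __init__(self, params, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _encode_labels(dataset: BeatDataset, cfg: TrainConfig) -> np.ndarray:
    """Integer labels; for detection every non-HC class maps to positive 1."""
    if cfg.task == "detection":
        return (dataset.labels != "HC").astype(int) \
            if "HC" in dataset.class_names \
            else (dataset.labels == cfg.class_names[1]).astype(int)
    name_to_idx = {c: i for i, c in enumerate(cfg.class_names)}
    return np.array([name_to_idx[l] for l in dataset.labels])


def evaluate_accuracy(model: MlaCnnBigru, dataset: BeatDataset,
                      cfg: TrainConfig) -> float:
    X, _, _ = dataset.to_arrays()
    y = _encode_labels(dataset, cfg)
    pred, _, _ = model.predict(X)
    return float(np.mean(pred == y))


def train(train_set: BeatDataset, val_set: BeatDataset | None,
          cfg: TrainConfig, model_config: ModelConfig | None = None,
          model: MlaCnnBigru | None = None,
          log=None) -> MlaCnnBigru:
    """Train a model for ``cfg.epochs``; returns the final-epoch model.

    ``model.history`` holds per-epoch mean training loss and validation
    accuracy (if a validation set is given).
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    if model is None:
        if model_config is None:
            model_config = ModelConfig(task=cfg.task,
                                       class_names=cfg.class_names,
                                       dropout=cfg.dropout)
        model = MlaCnnBigru(model_config, seed=cfg.seed)
    X, _, _ = train_set.to_arrays()
    y = _encode_labels(train_set, cfg)
    present = np.unique(y)
    expected = 2 if cfg.task == "detection" else len(cfg.class_names)
    if present.size < expected:
        import warnings
        warnings.warn("training set does not contain every class",
                      stacklevel=2)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = {"train_loss": [], "val_accuracy": []}
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_set))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            probs, _ = model.forward(X[idx], training=True, rng=rng)
            batch_loss = loss(probs, y[idx], cfg.task)
            if not np.isfinite(batch_loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {lo // cfg.batch_size}: "
                    f"{batch_loss.data!r} — lower the learning rate")
            model.zero_grad()
            batch_loss.backward()
            opt.step()
            losses.append(float(batch_loss.data))
            del probs, batch_loss  # release the tape before the next forward
        history["train_loss"].append(float(np.mean(losses)))
        if val_set is not None and len(val_set):
            history["val_accuracy"].append(
                evaluate_accuracy(model, val_set, cfg))
        if log is not None:
            va = history["val_accuracy"][-1] if history["val_accuracy"] else None
            log(epoch, history["train_loss"][-1], va)
    # final model's evaluation statistics (see recalibrate_batchnorm)
    model.recalibrate_batchnorm(X, cfg.batch_size)
    if val_set is not None and len(val_set):
        history["val_accuracy"].append(evaluate_accuracy(model, val_set, cfg))
    model.history = history
    return model


DEFAULT_GRID = {
    "dropout": [0.2, 0.3, 0.4],
    "learning_rate": [0.0008, 0.001],
    "batch_size": [16, 24, 32],
    "epochs": [10, 20, 30],
}


def grid_search(train_set: BeatDataset, val_set: BeatDataset,
                grid: dict | None = None, base_cfg: TrainConfig | None = None,
                model_config: ModelConfig | None = None):
    """Exhaustive hyperparameter search scored by validation accuracy.

    Ties break toward fewer epochs, then smaller batch size.  Returns
    ``(best_config, results)`` where results is one row per grid point.
    """
    grid = dict(grid or DEFAULT_GRID)
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    base_cfg = base_cfg or TrainConfig(epochs=5)
    keys = sorted(grid)
    rows = []
    best = None
    for values in itertools.product(*(grid[k] for k in keys)):
        cfg = dataclasses.replace(base_cfg, **dict(zip(keys, values)))
        mc = model_config
        if mc is not None and "dropout" in keys:
            mc = dataclasses.replace(mc, dropout=cfg.dropout)
        try:
            m = train(train_set, val_set, cfg, model_config=mc)
            acc = evaluate_accuracy(m, val_set, cfg)
        except RuntimeError:  # diverged (e.g. absurd learning rate)
            acc = float("nan")
        rows.append({**dict(zip(keys, values)), "val_accuracy": acc})
        score = (-acc if np.isfinite(acc) else np.inf,
                 cfg.epochs, cfg.batch_size)
        if best is None or score < best[0]:
            best = (score, cfg)
    return best[1], pd.DataFrame(rows)
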