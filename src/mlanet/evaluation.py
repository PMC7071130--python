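"""Evaluation protocol: Acc/Sen/Spe, five-fold splitting, lead weights.

Metrics follow the standard confusion-count definitions

    Acc = (TP + TN) / (TP + FP + TN + FN)
    Sen = TP / (TP + FN)        (true-positive rate; low missed diagnosis)
    Spe = TN / (FP + TN)        (true-negative rate; low misdiagnosis)

reported as percentages.  Cross-validation comes in two flavours:
*intra-patient* partitions beats directly (beats of one patient may land in
both train and test), while *inter-patient* partitions patients, the
clinically realistic protocol.  Both split into five near-equal parts and
rotate: three parts train, one validates, one tests (3:1:1).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io import BeatDataset
from .leads import LEAD_NAMES
from .model import ModelConfig
from .training import TrainConfig, _encode_labels, train


def confusion(y_true, y_pred, positive_class=1):
    """(TP, FP, TN, FN) with ``positive_class`` as the positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = set(np.unique(y_true)) | set(np.unique(y_pred))
    if positive_class not in labels and len(y_true):
        warnings.warn(f"positive class {positive_class!r} absent from labels",
                      stacklevel=2)
    tp = int(np.sum((y_true == positive_class) & (y_pred == positive_class)))
    fn = int(np.sum((y_true == positive_class) & (y_pred != positive_class)))
    fp = int(np.sum((y_true != positive_class) & (y_pred == positive_class)))
    tn = int(np.sum((y_true != positive_class) & (y_pred != positive_class)))
    return tp, fp, tn, fn


def acc_sen_spe(tp: int, fp: int, tn: int, fn: int):
    """(accuracy %, sensitivity %, specificity %); NaN on empty denominators."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    acc = 100.0 * (tp + tn) / total if total else float("nan")
    if tp + fn:
        sen = 100.0 * tp / (tp + fn)
    else:
        warnings.warn("no positive samples; sensitivity undefined", stacklevel=2)
        sen = float("nan")
    if tn + fp:
        spe = 100.0 * tn / (tn + fp)
    else:
        warnings.warn("no negative samples; specificity undefined", stacklevel=2)
        spe = float("nan")
    return acc, sen, spe


@dataclasses.dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    sen: float
    spe: float
    per_class: dict | None = None          # class -> {acc, sen, spe, counts}
    multiclass_accuracy: float | None = None

    @classmethod
    def from_counts(cls, tp, fp, tn, fn):
        acc, sen, spe = acc_sen_spe(tp, fp, tn, fn)
        return cls(tp, fp, tn, fn, acc, sen, spe)


def binary_metrics(y_true, y_pred, positive_class=1) -> MetricsReport:
    return MetricsReport.from_counts(*confusion(y_true, y_pred, positive_class))


def per_class_metrics(y_true, y_pred, class_names) -> MetricsReport:
    """One-vs-rest Sen/Spe per class plus the overall multi-class accuracy.

    Per-class "accuracy" in the one-vs-rest sense collapses to the shared
    multi-class fraction-correct when every class is scored on the same
    predictions, so both are exposed: ``multiclass_accuracy`` (the headline
    number) and the per-class one-vs-rest breakdown.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    overall = 100.0 * float(np.mean(y_true == y_pred)) if len(y_true) else float("nan")
    per_class = {}
    sens, spes = [], []
    for c in class_names:
        tp, fp, tn, fn = confusion(y_true, y_pred, positive_class=c)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            acc_c, sen_c, spe_c = acc_sen_spe(tp, fp, tn, fn)
        if tp + fn == 0:
            warnings.warn(f"class {c!r} absent from y_true; its sensitivity "
                          "is undefined", stacklevel=2)
        per_class[c] = {"acc": acc_c, "sen": sen_c, "spe": spe_c,
                        "counts": (tp, fp, tn, fn)}
        sens.append(sen_c)
        spes.append(spe_c)
    tp_all = sum(v["counts"][0] for v in per_class.values())
    fp_all = sum(v["counts"][1] for v in per_class.values())
    tn_all = sum(v["counts"][2] for v in per_class.values())
    fn_all = sum(v["counts"][3] for v in per_class.values())
    return MetricsReport(
        tp=tp_all, fp=fp_all, tn=tn_all, fn=fn_all,
        acc=overall,
        sen=float(np.nanmean(sens)),
        spe=float(np.nanmean(spes)),
        per_class=per_class,
        multiclass_accuracy=overall,
    )


# -- fold construction --------------------------------------------------------

@dataclasses.dataclass
class FoldSplit:
    fold_index: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    train_patients: tuple = ()
    val_patients: tuple = ()
    test_patients: tuple = ()


def _rotate_parts(parts, fold):
    """parts[fold] tests, parts[fold+1] validates, the rest train (3:1:1)."""
    k = len(parts)
    test = parts[fold]
    val = parts[(fold + 1) % k]
    train_parts = [parts[j] for j in range(k)
                   if j != fold and j != (fold + 1) % k]
    return np.concatenate(train_parts), val, test


def make_folds(dataset: BeatDataset, scheme: str = "intra", k: int = 5,
               seed: int = 0) -> list:
    """Five-fold splits; ``intra`` partitions beats, ``inter`` patients."""
    if scheme not in ("intra", "inter"):
        raise ValueError("scheme must be 'intra' or 'inter'")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    folds = []
    if scheme == "intra":
        parts = np.array_split(rng.permutation(n), k)
        for i in range(k):
            tr, va, te = _rotate_parts(parts, i)
            folds.append(FoldSplit(i, np.sort(tr), np.sort(va), np.sort(te)))
        return folds
    # inter-patient: partition patients per class (stratified), rotate
    pids = dataset.patient_ids
    labels = dataset.labels
    patient_class = {}
    for p, l in zip(pids, labels):
        patient_class[p] = l
    class_parts: list[list] = [[] for _ in range(k)]
    for cls in sorted(set(patient_class.values())):
        cls_patients = sorted(p for p, l in patient_class.items() if l == cls)
        if len(cls_patients) < k:
            raise ValueError(
                f"inter-patient scheme needs >= {k} patients per class; "
                f"class {cls!r} has {len(cls_patients)}")
        perm = rng.permutation(len(cls_patients))
        for j, part in enumerate(np.array_split(perm, k)):
            class_parts[j].extend(cls_patients[idx] for idx in part)
    pid_to_beats: dict = {}
    for i, p in enumerate(pids):
        pid_to_beats.setdefault(p, []).append(i)
    for i in range(k):
        tr_p, va_p, te_p = _rotate_parts(
            [np.array(part, dtype=object) for part in class_parts], i)
        tr = np.sort(np.concatenate([pid_to_beats[p] for p in tr_p]))
        va = np.sort(np.concatenate([pid_to_beats[p] for p in va_p]))
        te = np.sort(np.concatenate([pid_to_beats[p] for p in te_p]))
        folds.append(FoldSplit(i, tr, va, te,
                               tuple(tr_p), tuple(va_p), tuple(te_p)))
    return folds


# -- cross-validation ---------------------------------------------------------

@dataclasses.dataclass
class CrossValidationResult:
    fold_reports: list
    lead_weights: np.ndarray       # (k_folds, 12): mean alpha1 over test beats
    mean: dict                     # metric -> mean over folds
    std: dict                      # metric -> population std over folds

    @property
    def mean_lead_weights(self) -> np.ndarray:
        return self.lead_weights.mean(axis=0)

    def lead_weight_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lead": LEAD_NAMES,
                             "mean_weight": self.mean_lead_weights})


def _summary(fold_reports):
    mean, std = {}, {}
    for key in ("acc", "sen", "spe"):
        vals = np.array([getattr(r, key) for r in fold_reports], dtype=float)
        mean[key] = float(np.nanmean(vals))
        std[key] = float(np.nanstd(vals))  # population std over the folds
    return mean, std


def cross_validate(dataset: BeatDataset, cfg: TrainConfig,
                   scheme: str = "intra",
                   model_config: ModelConfig | None = None, k: int = 5,
                   log=None) -> CrossValidationResult:
    """Train and evaluate per fold; aggregate metrics and MLA lead weights.

    Lead weights are the mean alpha1 over each fold's test beats (the
    evaluation beats), then averaged across folds by the caller via
    ``mean_lead_weights``.
    """
    folds = make_folds(dataset, scheme, k, cfg.seed)
    reports = []
    weights = np.zeros((len(folds), len(LEAD_NAMES)))
    for split in folds:
        tr = dataset.subset(split.train_idx)
        va = dataset.subset(split.val_idx)
        te = dataset.subset(split.test_idx)
        # independent initialization per fold: fold summaries then average
        # over five model draws rather than repeating one
        fold_cfg = dataclasses.replace(cfg, seed=cfg.seed + split.fold_index)
        model = train(tr, va, fold_cfg, model_config=model_config,
                      log=(lambda e, l, a, f=split.fold_index:
                           log(f, e, l, a)) if log else None)
        X_te, _, _ = te.to_arrays()
        y_te = _encode_labels(te, cfg)
        pred, _, alpha1 = model.predict(X_te)
        if cfg.task == "detection":
            reports.append(binary_metrics(y_te, pred, positive_class=1))
        else:
            reports.append(per_class_metrics(
                y_te, pred, list(range(len(cfg.class_names)))))
        weights[split.fold_index] = alpha1.mean(axis=0)
    mean, std = _summary(reports)
    return CrossValidationResult(reports, weights, mean, std)
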